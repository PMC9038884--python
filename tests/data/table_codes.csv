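# Transcription of the published consensus code tables: every printed
# diagnosis code with the canonical set(s) it is assigned to.
# Columns: system,code,sets (semicolon-joined; empty = member of no set).
system,code,sets
ICD9CM,491.0,copd
ICD9CM,491.1,copd
ICD9CM,491.8,copd
ICD9CM,491.9,copd
ICD9CM,491.20,copd
ICD9CM,491.21,copd
ICD9CM,491.22,copd
ICD9CM,492.0,copd
ICD9CM,492.8,copd
ICD9CM,496,copd
ICD10CM,J41.0,copd
ICD10CM,J41.1,copd
ICD10CM,J41.8,copd
ICD10CM,J42,copd
ICD10CM,J43.0,copd
ICD10CM,J43.1,copd
ICD10CM,J43.2,copd
ICD10CM,J43.8,copd
ICD10CM,J43.9,copd
ICD10CM,J44.0,copd
ICD10CM,J44.1,copd
ICD10CM,J44.9,copd
ICD9CM,517.1,ild
ICD10CM,J17,ild
ICD9CM,500,ild
ICD10CM,J60,ild
ICD9CM,501,ild
ICD10CM,J61,ild
ICD10CM,J62.0,ild
ICD9CM,502,ild
ICD10CM,J62.8,ild
ICD9CM,503,ild
ICD10CM,J63.0,ild
ICD10CM,J63.1,ild
ICD10CM,J63.2,ild
ICD10CM,J63.3,ild
ICD10CM,J63.4,ild
ICD10CM,J63.5,ild
ICD10CM,J63.6,ild
ICD9CM,505,ild
ICD10CM,J64,ild
ICD10CM,J65,ild
ICD9CM,504,ild
ICD10CM,J66,ild
ICD10CM,J66.0,ild
ICD10CM,J66.1,ild
ICD10CM,J66.2,ild
ICD10CM,J66.8,ild
ICD9CM,495,ild
ICD10CM,J67,ild
ICD9CM,495.0,ild
ICD10CM,J67.0,ild
ICD9CM,495.1,ild
ICD10CM,J67.1,ild
ICD9CM,495.2,ild
ICD10CM,J67.2,ild
ICD9CM,495.3,ild
ICD10CM,J67.3,ild
ICD9CM,495.4,ild
ICD10CM,J67.4,ild
ICD9CM,495.5,ild
ICD10CM,J67.5,ild
ICD9CM,495.6,ild
ICD10CM,J67.6,ild
ICD9CM,495.7,ild
ICD10CM,J67.7,ild
ICD9CM,495.8,ild
ICD10CM,J67.8,ild
ICD9CM,495.9,ild
ICD10CM,J67.9,ild
ICD9CM,506,ild
ICD10CM,J68,ild
ICD9CM,506.4,ild
ICD10CM,J68.4,ild
ICD9CM,506.9,ild
ICD10CM,J68.9,ild
ICD9CM,508.1,ild
ICD10CM,J70.1,ild
ICD10CM,J70.3,ild
ICD10CM,J70.4,ild
ICD9CM,508.8,ild
ICD10CM,J70.8,ild
ICD9CM,518.3,ild
ICD10CM,J82,ild
ICD9CM,516.2,ild
ICD10CM,J84.02,ild
ICD9CM,516.1,ild
ICD10CM,J84.03,ild
ICD9CM,515,ild
ICD10CM,J84.10,ild
ICD9CM,516.8,ild
ICD10CM,J84.11,ild
ICD9CM,516.30,ild
ICD10CM,J84.111,ild
ICD9CM,516.31,ild
ICD10CM,J84.112,ild
ICD9CM,516.32,ild
ICD10CM,J84.113,ild
ICD9CM,516.33,ild
ICD10CM,J84.114,ild
ICD9CM,516.34,ild
ICD10CM,J84.115,ild
ICD9CM,516.36,ild
ICD10CM,J84.116,ild
ICD9CM,516.37,ild
ICD10CM,J84.117,ild
ICD10CM,J84.17,ild
ICD9CM,516.35,ild
ICD10CM,J84.2,ild
ICD10CM,J84.89,ild
ICD9CM,516.9,ild
ICD10CM,J84.9,ild
ICD9CM,710.0,ild;ctd_lung
ICD10CM,M32.13,ild;ctd_lung
ICD9CM,710.1,ild;ctd_lung
ICD10CM,M34.81,ild;ctd_lung
ICD9CM,710.3,ild;ctd_lung
ICD10CM,M33.01,ild;ctd_lung
ICD10CM,M33.11,ild;ctd_lung
ICD9CM,710.4,ild;ctd_lung
ICD10CM,M33.21,ild;ctd_lung
ICD10CM,M33.91,ild;ctd_lung
ICD9CM,714.81,ild;ctd_lung
ICD10CM,M05.1,ild;ctd_lung
ICD10CM,M05.10,ild;ctd_lung
ICD10CM,M05.11,ild;ctd_lung
ICD10CM,M05.111,ild;ctd_lung
ICD10CM,M05.112,ild;ctd_lung
ICD10CM,M05.119,ild;ctd_lung
ICD10CM,M05.12,ild;ctd_lung
ICD10CM,M05.121,ild;ctd_lung
ICD10CM,M05.122,ild;ctd_lung
ICD10CM,M05.129,ild;ctd_lung
ICD10CM,M05.13,ild;ctd_lung
ICD10CM,M05.131,ild;ctd_lung
ICD10CM,M05.132,ild;ctd_lung
ICD10CM,M05.139,ild;ctd_lung
ICD10CM,M05.14,ild;ctd_lung
ICD10CM,M05.141,ild;ctd_lung
ICD10CM,M05.142,ild;ctd_lung
ICD10CM,M05.149,ild;ctd_lung
ICD10CM,M05.15,ild;ctd_lung
ICD10CM,M05.151,ild;ctd_lung
ICD10CM,M05.152,ild;ctd_lung
ICD10CM,M05.159,ild;ctd_lung
ICD10CM,M05.16,ild;ctd_lung
ICD10CM,M05.161,ild;ctd_lung
ICD10CM,M05.162,ild;ctd_lung
ICD10CM,M05.169,ild;ctd_lung
ICD10CM,M05.17,ild;ctd_lung
ICD10CM,M05.171,ild;ctd_lung
ICD10CM,M05.172,ild;ctd_lung
ICD10CM,M05.179,ild;ctd_lung
ICD10CM,M05.19,ild;ctd_lung
ICD9CM,416,ph
ICD10CM,I27,ph
ICD9CM,416.0,ph
ICD10CM,I27.0,ph
ICD9CM,416.8,ph
ICD10CM,I27.2,ph
ICD10CM,I27.20,ph
ICD10CM,I27.21,ph
ICD10CM,I27.23,ph
ICD10CM,I27.29,ph
ICD10CM,I27.89,ph
ICD9CM,416.9,ph
ICD10CM,I27.81,ph
ICD10CM,I27.9,ph
ICD9CM,995.29,excl_group1
ICD10CM,T50.5X50,excl_group1
ICD9CM,042,excl_group1
ICD10CM,B20,excl_group1
ICD9CM,572.3,excl_group1
ICD10CM,K76.6,excl_group1
ICD9CM,745.5,excl_group1
ICD10CM,Q21.1,excl_group1
ICD9CM,745.4,excl_group1
ICD10CM,Q21.0,excl_group1
ICD9CM,120,excl_group1
ICD10CM,B65,excl_group1
ICD9CM,120.0,excl_group1
ICD10CM,B65.1,excl_group1
ICD9CM,414.10,excl_group2
ICD10CM,I25.3,excl_group2
ICD10CM,I27.22,excl_group2
ICD9CM,425.3,excl_group2
ICD10CM,I42.4,excl_group2
ICD9CM,428.1,excl_group2
ICD10CM,I50.1,excl_group2
ICD9CM,428.2,excl_group2
ICD10CM,I50.22,excl_group2
ICD9CM,428.3,excl_group2
ICD10CM,I50.3,excl_group2
ICD9CM,394,excl_group2
ICD9CM,424.0,excl_group2
ICD10CM,I34.0,excl_group2
ICD10CM,I34.8,excl_group2
ICD9CM,395,excl_group2
ICD9CM,424.1,excl_group2
ICD10CM,I35,excl_group2
ICD10CM,I35.0,excl_group2
ICD9CM,396,excl_group2
ICD10CM,I08,excl_group2
ICD9CM,746.3,excl_group2
ICD9CM,746.4,excl_group2
ICD9CM,746.5,excl_group2
ICD9CM,746.6,excl_group2
ICD9CM,746.7,excl_group2
ICD9CM,746.81,excl_group2
ICD9CM,425.1,excl_group2
ICD10CM,I42.1,excl_group2
ICD9CM,425.8,excl_group2
ICD10CM,I43,excl_group2
ICD9CM,746.8,excl_group2
ICD10CM,Q24,excl_group2;excl_group5
ICD9CM,402.01,excl_group2
ICD9CM,402.11,excl_group2
ICD9CM,402.91,excl_group2
ICD10CM,I11.0,excl_group2
ICD9CM,404.01,excl_group2
ICD9CM,404.03,excl_group2
ICD9CM,404.11,excl_group2
ICD9CM,404.13,excl_group2
ICD9CM,404.91,excl_group2
ICD9CM,404.93,excl_group2
ICD10CM,I13.0,excl_group2
ICD10CM,I13.2,excl_group2
ICD10CM,Q23,excl_group2;excl_group5
ICD9CM,327.24,excl_group3_other
ICD10CM,G47.34,excl_group3_other
ICD9CM,327.25,excl_group3_other
ICD10CM,G47.35,excl_group3_other
ICD9CM,E902.0,excl_group3_other
ICD10CM,W94.11XA,excl_group3_other
ICD10CM,W94.11XD,excl_group3_other
ICD10CM,W94.11XS,excl_group3_other
ICD9CM,993.2,excl_group3_other
ICD9CM,519.2,excl_group3_other;excl_group5
ICD10CM,J98.15,excl_group3_other
ICD9CM,756.6,excl_group3_other
ICD10CM,Q79.0,excl_group3_other
ICD9CM,770.7,excl_group3_other
ICD10CM,P27.1,excl_group3_other
ICD9CM,516.64,excl_group3_other
ICD10CM,J84.843,excl_group3_other
ICD9CM,748.5,excl_group3_other
ICD10CM,Q33.3,excl_group3_other
ICD10CM,Q33.6,excl_group3_other
ICD9CM,516.63,excl_group3_other
ICD10CM,J84.83,excl_group3_other
ICD9CM,516.62,excl_group3_other
ICD10CM,J84.842,excl_group3_other
ICD9CM,516.0,excl_group3_other
ICD10CM,J84.01,excl_group3_other
ICD9CM,516.69,excl_group3_other
ICD10CM,J84.848,excl_group3_other
ICD9CM,415.1,excl_group4
ICD10CM,I26.99,excl_group4
ICD10CM,I26.90,excl_group4
ICD9CM,416.2,excl_group4
ICD10CM,I27.24,excl_group4
ICD10CM,I27.82,excl_group4
ICD9CM,V12.51,excl_group4
ICD10CM,Z86.718,excl_group4
ICD9CM,282,excl_group5
ICD10CM,D55,excl_group5
ICD9CM,283,excl_group5
ICD10CM,D56,excl_group5
ICD9CM,283.4,excl_group5
ICD10CM,D57,excl_group5
ICD9CM,238.79,excl_group5
ICD10CM,D58,excl_group5
ICD9CM,135,excl_group5
ICD10CM,D86,excl_group5
ICD9CM,277.89,excl_group5
ICD10CM,E88.89,excl_group5
ICD9CM,202.5,excl_group5
ICD10CM,C96.0,excl_group5
ICD9CM,228.1,excl_group5
ICD10CM,D18.1,excl_group5
ICD9CM,271,excl_group5
ICD10CM,E74,excl_group5
ICD9CM,272.7,excl_group5
ICD10CM,E75.22,excl_group5
ICD10CM,J98.51,excl_group5
ICD9CM,746,excl_group5
ICD10CM,Q22,excl_group5
ICD10CM,G47.33,
ICD9CM,327.23,
ICD10CM,I50.9,
ICD9CM,428.0,
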