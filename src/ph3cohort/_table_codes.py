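"""Built-in diagnosis code tables for the Group 3 PH phenotype.

Each entry is (system, code-as-printed, match_mode).  Codes are stored here
in dotted clinical notation; :mod:`ph3cohort.codesets` normalizes them
(uppercase, dot stripped) on registry construction.

match_mode "prefix" is used only where the clinical source notation carries
a trailing ".x" wildcard (whole-family codes); every fully specified code,
including three-character category parents printed on their own, is "exact".
"""

E = "exact"
P = "prefix"
I9 = "ICD9CM"
I10 = "ICD10CM"

# --- chronic obstructive pulmonary disease -------------------------------
COPD = [
    (I9, "491.0", E), (I9, "491.1", E), (I9, "491.8", E), (I9, "491.9", E),
    (I9, "491.20", E), (I9, "491.21", E), (I9, "491.22", E),
    (I9, "492.0", E), (I9, "492.8", E), (I9, "496", E),
    (I10, "J41.0", E), (I10, "J41.1", E), (I10, "J41.8", E), (I10, "J42", E),
    (I10, "J43.0", E), (I10, "J43.1", E), (I10, "J43.2", E), (I10, "J43.8", E),
    (I10, "J43.9", E),
    (I10, "J44.0", E), (I10, "J44.1", E), (I10, "J44.9", E),
]

# --- interstitial lung disease: connective tissue disease with lung
#     involvement (subset of ILD, also its own set for COPD-only studies) --
CTD_LUNG = [
    (I9, "710.0", E), (I9, "710.1", E), (I9, "710.3", E), (I9, "710.4", E),
    (I9, "714.81", E),
    (I10, "M32.13", E), (I10, "M34.81", E),
    (I10, "M33.01", E), (I10, "M33.11", E), (I10, "M33.21", E), (I10, "M33.91", E),
    (I10, "M05.1", E), (I10, "M05.10", E),
    (I10, "M05.11", E), (I10, "M05.111", E), (I10, "M05.112", E), (I10, "M05.119", E),
    (I10, "M05.12", E), (I10, "M05.121", E), (I10, "M05.122", E), (I10, "M05.129", E),
    (I10, "M05.13", E), (I10, "M05.131", E), (I10, "M05.132", E), (I10, "M05.139", E),
    (I10, "M05.14", E), (I10, "M05.141", E), (I10, "M05.142", E), (I10, "M05.149", E),
    (I10, "M05.15", E), (I10, "M05.151", E), (I10, "M05.152", E), (I10, "M05.159", E),
    (I10, "M05.16", E), (I10, "M05.161", E), (I10, "M05.162", E), (I10, "M05.169", E),
    (I10, "M05.17", E), (I10, "M05.171", E), (I10, "M05.172", E), (I10, "M05.179", E),
    (I10, "M05.19", E),
]

# --- interstitial lung disease (full set; includes CTD_LUNG) -------------
ILD = [
    (I9, "517.1", E), (I10, "J17", E),
    (I9, "500", E), (I10, "J60", E),
    (I9, "501", E), (I10, "J61", E),
    (I10, "J62.0", E),
    (I9, "502", E), (I10, "J62.8", E),
    (I9, "503", E),
    (I10, "J63.0", E), (I10, "J63.1", E), (I10, "J63.2", E), (I10, "J63.3", E),
    (I10, "J63.4", E), (I10, "J63.5", E), (I10, "J63.6", E),
    (I9, "505", E), (I10, "J64", E), (I10, "J65", E),
    (I9, "504", E), (I10, "J66", E),
    (I10, "J66.0", E), (I10, "J66.1", E), (I10, "J66.2", E), (I10, "J66.8", E),
    (I9, "495", E), (I10, "J67", E),
    (I9, "495.0", E), (I10, "J67.0", E),
    (I9, "495.1", E), (I10, "J67.1", E),
    (I9, "495.2", E), (I10, "J67.2", E),
    (I9, "495.3", E), (I10, "J67.3", E),
    (I9, "495.4", E), (I10, "J67.4", E),
    (I9, "495.5", E), (I10, "J67.5", E),
    (I9, "495.6", E), (I10, "J67.6", E),
    (I9, "495.7", E), (I10, "J67.7", E),
    (I9, "495.8", E), (I10, "J67.8", E),
    (I9, "495.9", E), (I10, "J67.9", E),
    (I9, "506", E), (I10, "J68", E),
    (I9, "506.4", E), (I10, "J68.4", E),
    (I9, "506.9", E), (I10, "J68.9", E),
    (I9, "508.1", E), (I10, "J70.1", E),
    (I10, "J70.3", E), (I10, "J70.4", E),
    (I9, "508.8", E), (I10, "J70.8", E),
    (I9, "518.3", E), (I10, "J82", E),
    (I9, "516.2", E), (I10, "J84.02", E),
    (I9, "516.1", E), (I10, "J84.03", E),
    (I9, "515", E), (I10, "J84.10", E),
    (I9, "516.8", E), (I10, "J84.11", E),
    (I9, "516.30", E), (I10, "J84.111", E),
    (I9, "516.31", E), (I10, "J84.112", E),
    (I9, "516.32", E), (I10, "J84.113", E),
    (I9, "516.33", E), (I10, "J84.114", E),
    (I9, "516.34", E), (I10, "J84.115", E),
    (I9, "516.36", E), (I10, "J84.116", E),
    (I9, "516.37", E), (I10, "J84.117", E),
    (I10, "J84.17", E),
    (I9, "516.35", E), (I10, "J84.2", E),
    (I10, "J84.89", E),
    (I9, "516.9", E), (I10, "J84.9", E),
] + CTD_LUNG

# --- pulmonary hypertension ----------------------------------------------
# Three-character parents (416, I27) are exact here; the "broad" registry
# variant promotes them to prefixes.  Exclusion-only I27 children (I27.22,
# I27.24, I27.82) deliberately do NOT appear in this set.
PH = [
    (I9, "416", E), (I10, "I27", E),
    (I9, "416.0", E), (I10, "I27.0", E),
    (I9, "416.8", E), (I10, "I27.2", E),
    (I10, "I27.20", E), (I10, "I27.21", E), (I10, "I27.23", E),
    (I10, "I27.29", E), (I10, "I27.89", E),
    (I9, "416.9", E), (I10, "I27.81", E), (I10, "I27.9", E),
]

# --- exclusion sets: other PH clinical groups ----------------------------
EXCL_GROUP1 = [  # pulmonary arterial hypertension
    (I9, "995.29", E), (I10, "T50.5X50", E),
    (I9, "042", E), (I10, "B20", E),
    (I9, "572.3", E), (I10, "K76.6", E),
    (I9, "745.5", E), (I10, "Q21.1", E),
    (I9, "745.4", E), (I10, "Q21.0", E),
    (I9, "120", P), (I10, "B65", P),       # schistosomiasis families
]

EXCL_GROUP2 = [  # PH with left heart disease
    (I9, "414.10", E), (I10, "I25.3", E),
    (I10, "I27.22", E),
    (I9, "425.3", E), (I10, "I42.4", E),
    (I9, "428.1", E), (I10, "I50.1", E),
    (I9, "428.2", E), (I10, "I50.22", E),
    (I9, "428.3", E), (I10, "I50.3", E),
    (I9, "394", E), (I9, "424.0", E), (I10, "I34.0", E), (I10, "I34.8", E),
    (I9, "395", E), (I9, "424.1", E), (I10, "I35", P),   # aortic valve family
    (I9, "396", E), (I10, "I08", E),
    (I9, "746.3", E), (I9, "746.4", E), (I9, "746.5", E), (I9, "746.6", E),
    (I9, "746.7", E), (I9, "746.81", E), (I10, "Q23", E),
    (I9, "425.1", E), (I10, "I42.1", E),
    (I9, "425.8", E), (I10, "I43", E),
    (I9, "746.8", E), (I10, "Q24", E),
    (I9, "402.01", E), (I9, "402.11", E), (I9, "402.91", E), (I10, "I11.0", E),
    (I9, "404.01", E), (I9, "404.03", E), (I9, "404.11", E), (I9, "404.13", E),
    (I9, "404.91", E), (I9, "404.93", E), (I10, "I13.0", E), (I10, "I13.2", E),
]

EXCL_GROUP3_OTHER = [  # other Group 3 lung diseases (not COPD/ILD)
    (I9, "327.24", E), (I10, "G47.34", E),
    (I9, "327.25", E), (I10, "G47.35", E),
    (I9, "E902.0", E),
    (I10, "W94.11XA", E), (I10, "W94.11XD", E), (I10, "W94.11XS", E),
    (I9, "993.2", E),
    (I9, "519.2", E), (I10, "J98.15", E),
    (I9, "756.6", E), (I10, "Q79.0", E),
    (I9, "770.7", E), (I10, "P27.1", E),
    (I9, "516.64", E), (I10, "J84.843", E),
    (I9, "748.5", E), (I10, "Q33.3", E), (I10, "Q33.6", E),
    (I9, "516.63", E), (I10, "J84.83", E),
    (I9, "516.62", E), (I10, "J84.842", E),
    (I9, "516.0", E), (I10, "J84.01", E),
    (I9, "516.69", E), (I10, "J84.848", E),
]

EXCL_GROUP4 = [  # chronic thromboembolic PH
    (I9, "415.1", E), (I10, "I26.99", E), (I10, "I26.90", E),
    (I9, "416.2", E), (I10, "I27.24", E), (I10, "I27.82", E),
    (I9, "V12.51", E), (I10, "Z86.718", E),
]

EXCL_GROUP5 = [  # PH with unclear multifactorial mechanisms
    (I9, "282", E), (I10, "D55", E),
    (I9, "283", E), (I10, "D56", E),
    (I9, "283.4", E), (I10, "D57", E),
    (I9, "238.79", E), (I10, "D58", E),
    (I9, "135", E), (I10, "D86", E),
    (I9, "277.89", E), (I10, "E88.89", E),
    (I9, "202.5", E), (I10, "C96.0", E),
    (I9, "228.1", E), (I10, "D18.1", E),
    (I9, "271", E), (I10, "E74", E),
    (I9, "272.7", E), (I10, "E75.22", E),
    (I9, "519.2", E), (I10, "J98.51", E),
    (I9, "746", E), (I10, "Q22", E), (I10, "Q23", E), (I10, "Q24", E),
]

# --- study-preset support sets (not part of the canonical tables) --------
PRESET_SETS = {
    # idiopathic pulmonary fibrosis family (516.3 and 5-digit children)
    "collard_ipf": [(I9, "516.3", P)],
    "ph_416_0": [(I9, "416.0", E)],
    "ph_416_0x": [(I9, "416.0", P)],
    "ph_416_narrow": [(I9, "416.0", E), (I9, "416.8", E)],
    "medrek_copd": [(I9, "491", P), (I9, "492", P), (I9, "494", P), (I9, "496", P)],
    "pedraza_ild": [
        (I9, "516.31", E), (I9, "495.9", E), (I9, "516.36", E),
        (I9, "516.4", E), (I9, "516.5", E), (I9, "135", E),
    ],
    # approximated with CM codes; source study used 4-digit non-CM codes
    "wijeratne_ph": [
        (I9, "416.0", E), (I9, "416.1", E), (I9, "416.8", E), (I9, "416.9", E),
        (I10, "I27.0", E), (I10, "I27.1", E), (I10, "I27.2", P),
        (I10, "I27.8", P), (I10, "I27.9", E),
    ],
    # systemic sclerosis, excluding the CREST form (M34.2)
    "butt_ssc": [
        (I10, "M34.0", E), (I10, "M34.1", E), (I10, "M34.8", P), (I10, "M34.9", E),
    ],
    "butt_ph": [(I10, "I27", P)],
    "hemnes_ph": [
        (I9, "416.0", E), (I9, "416.8", E),
        (I10, "I27.0", E), (I10, "I27.20", E), (I10, "I27.21", E),
        (I10, "I27.23", E), (I10, "I27.24", E), (I10, "I27.29", E), (I10, "I27.89", E),
    ],
    "trammell_ph": [
        (I9, "416.0", E), (I9, "416.2", E), (I9, "416.8", E), (I9, "416.9", E),
    ],
    "wu_copd": [(I9, "490", P), (I9, "491", P), (I9, "492", P), (I9, "496", P)],
    "wu_ph": [
        (I9, "416.0", E), (I9, "416.8", E), (I9, "416.9", E),
        (I10, "I27.0", E), (I10, "I27.2", P), (I10, "I27.8", P), (I10, "I27.9", E),
    ],
    "wu_sleep_apnea": [(I9, "327.23", E), (I9, "780.57", E), (I10, "G47.33", E)],
}

CANONICAL_SETS = {
    "copd": (COPD, "Chronic obstructive pulmonary disease"),
    "ild": (ILD, "Interstitial lung disease (incl. CTD with lung involvement)"),
    "ctd_lung": (CTD_LUNG, "Connective tissue disease with lung involvement"),
    "ph": (PH, "Pulmonary hypertension"),
    "excl_group1": (EXCL_GROUP1, "Group 1 PAH exclusions"),
    "excl_group2": (EXCL_GROUP2, "Group 2 left-heart-disease PH exclusions"),
    "excl_group3_other": (EXCL_GROUP3_OTHER, "Other Group 3 lung disease exclusions"),
    "excl_group4": (EXCL_GROUP4, "Group 4 CTEPH exclusions"),
    "excl_group5": (EXCL_GROUP5, "Group 5 multifactorial PH exclusions"),
}

REGISTRY_VERSION = "2022.1"
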