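patient_id,claim_id,service_date,setting,dx_position,dx_code,dx_system,proc_code
A,A1,2014-03-02,outpatient,1,496,,
A,A1,2014-03-02,outpatient,2,401.9,,
A,A2,2014-05-10,outpatient,1,491.21,ICD9CM,
A,A3,2016-02-01,inpatient,1,I27.23,ICD10CM,
B,B1,2016-06-15,emergency,1,J44.9,,
B,B2,2016-08-01,outpatient,1,i27.21,,93451
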