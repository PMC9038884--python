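patient_id,birth_year,start_date,end_date
A,1949,2013-01-01,2013-12-31
A,1949,2014-01-01,2016-12-31
B,1955,2015-06-01,2017-05-31
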