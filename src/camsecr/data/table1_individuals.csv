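ID,age_class,sex,total_captures,n_capture_locations
AF1,adult,female,6,3
AF2,adult,female,11,4
AF3,adult,female,4,1
AF4,adult,female,2,1
AF5,adult,female,4,2
AF6,adult,female,1,1
AF7,adult,female,1,1
AM1,adult,male,2,1
AM2,adult,male,10,6
AM3,adult,male,14,3
JF1,juvenile,female,5,1
JF2,juvenile,female,4,1
JM1,juvenile,male,2,2
JM2,juvenile,male,3,1
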