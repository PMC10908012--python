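cohort,state,count
60s,STABLE,548
60s,NO_MGMT,519
60s,READMIT_COPD,118
60s,READMIT_RESP,108
60s,READMIT_OTHER,285
70s,STABLE,892
70s,NO_MGMT,875
70s,READMIT_COPD,240
70s,READMIT_RESP,245
70s,READMIT_OTHER,635
80s,STABLE,414
80s,NO_MGMT,530
80s,READMIT_COPD,175
80s,READMIT_RESP,172
80s,READMIT_OTHER,410
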