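state,annual_ratio,period_ratio,period_years
STABLE,1.0,,
NO_MGMT,1.328,2.34,3
READMIT_COPD,1.66,,
READMIT_RESP,1.091,1.14,1.5
READMIT_OTHER,1.117,1.18,1.5
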