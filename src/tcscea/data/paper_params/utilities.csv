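state,point,low,high
STABLE,0.795,0.716,0.875
NO_MGMT,0.795,0.716,0.875
READMIT_COPD,0.61,0.549,0.671
READMIT_RESP,0.52,0.468,0.572
READMIT_OTHER,0.440,0.396,0.484
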