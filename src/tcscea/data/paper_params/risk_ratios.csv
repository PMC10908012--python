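state,point,range_low,range_high,ci_low,ci_high
NO_MGMT,0.704,0.634,0.774,,
READMIT_COPD,0.599,0.539,0.659,0.421,0.852
READMIT_RESP,0.720,0.648,0.792,0.531,0.978
READMIT_OTHER,0.720,0.648,0.792,0.531,0.978
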