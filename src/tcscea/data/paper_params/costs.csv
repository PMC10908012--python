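cohort,state,total,reimbursed,non_reimbursed,nursing_fee,inhaler
60s,STABLE,76.20,0,0,0,76.20
60s,NO_MGMT,0,0,0,0,0
60s,READMIT_COPD,2395.13,1245.09,266.05,883.99,0
60s,READMIT_RESP,2931.74,1906.45,407.36,617.93,0
60s,READMIT_OTHER,2976.15,1907.68,407.63,660.85,0
70s,STABLE,100.18,0,0,0,100.18
70s,NO_MGMT,0,0,0,0,0
70s,READMIT_COPD,2467.40,1304.64,278.77,883.99,0
70s,READMIT_RESP,3078.42,2027.30,433.18,617.93,0
70s,READMIT_OTHER,2933.76,1872.75,400.16,660.85,0
80s,STABLE,98.09,0,0,0,98.09
80s,NO_MGMT,0,0,0,0,0
80s,READMIT_COPD,2556.49,1378.05,294.46,883.99,0
80s,READMIT_RESP,3147.07,2083.87,445.27,617.93,0
80s,READMIT_OTHER,2822.57,1781.14,380.58,660.85,0
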