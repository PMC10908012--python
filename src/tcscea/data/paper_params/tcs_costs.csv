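intervention,quantity,unit_cost_usd
Screening,0.5 h,7.68
Ward visit - baseline evaluation and EMR confirmation,2 h,30.73
Record evaluation result and set care plan,0.5 h,7.68
Education,1 h,15.37
Ward visit - build rapport,10 min x 3,7.68
Home visit within 48 h after discharge,1.5 h,23.05
Phone call visit once a week for 4 weeks,20 min x 4,20.44
Home visit - post evaluation and EMR confirmation after one month,1.5 h,23.05
Hospital visit - follow-up evaluation and EMR confirmation after three months,1.5 h,23.05
Business trip expense for two home visits,46.26 USD x 2,92.52
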