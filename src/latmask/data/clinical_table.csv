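observer,sex,age,age_started,prior_attack,frequency_per_month,excluded
OB8,F,23,16,1 month,1-3,0
OB12,F,27,10,2 weeks,1-3,0
OB14,F,60,19,3 months,<1,0
OB16,F,52,14,5 days,1-3,0
OB17,F,22,17,5 days,1-3,0
OB20,M,30,12,4 months,5 or more,0
OB21,F,41,24,9 days,5 or more,0
OB22,F,21,10,4 days,<1,0
OB24,F,36,23,7 days,1-3,0
OB25,F,29,3,20 days,1-3,0
OB28,F,30,13,3 months,<1,0
OB29,F,55,40,6 days,1-3,0
OB30,F,25,9,8 days,1-3,0
OB31,F,23,19,1 month,1-3,0
OB33,M,20,12,7 days,1-3,0
OB48,F,18,NDI,1 month,5 or more,0
OB50,F,21,NDI,7 days,<1,0
OB63,F,18,13,1 month,1-3,0
OB64,F,19,17,7 days,5 or more,0
OB66,F,19,16,A few months,1-3,0
OB71,F,20,11,> 3 days,<1,0
OB73,F,18,15,6 days,5 or more,0
OB75,F,19,16,3 months,<1,0
OB76,F,18,NDI,> 3 days,NDI,0
Excluded,F,19,16,1 day,1-3,1
Excluded,F,18,14,2 days,1-3,1
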