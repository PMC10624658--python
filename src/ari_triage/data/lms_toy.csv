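# Toy (synthetic) LMS growth reference for demonstration and testing only.
# NOT a WHO growth standard. Real reference tables can be dropped in as a
# CSV with the same schema: kind,sex,age_months,L,M,S.
# Values are smooth, roughly realistic medians for weight (kg), height (cm)
# and MUAC (cm) over 0-24 months, with constant-ish L and S by kind.
kind,sex,age_months,L,M,S
weight,M,0,0.35,3.35,0.146
weight,M,3,0.20,6.40,0.125
weight,M,6,0.12,7.93,0.119
weight,M,9,0.07,9.00,0.117
weight,M,12,0.04,9.65,0.117
weight,M,18,-0.01,10.90,0.120
weight,M,24,-0.05,12.15,0.124
weight,F,0,0.38,3.23,0.143
weight,F,3,0.17,5.85,0.124
weight,F,6,0.10,7.30,0.121
weight,F,9,0.05,8.30,0.120
weight,F,12,0.01,8.95,0.121
weight,F,18,-0.04,10.25,0.125
weight,F,24,-0.08,11.50,0.129
height,M,0,1.0,49.9,0.038
height,M,3,1.0,61.4,0.034
height,M,6,1.0,67.6,0.033
height,M,9,1.0,72.0,0.032
height,M,12,1.0,75.7,0.032
height,M,18,1.0,82.3,0.033
height,M,24,1.0,87.8,0.034
height,F,0,1.0,49.1,0.038
height,F,3,1.0,59.8,0.035
height,F,6,1.0,65.7,0.034
height,F,9,1.0,70.1,0.033
height,F,12,1.0,74.0,0.033
height,F,18,1.0,80.7,0.034
height,F,24,1.0,86.4,0.035
muac,M,3,0.7,13.4,0.082
muac,M,6,0.6,14.1,0.081
muac,M,9,0.5,14.5,0.081
muac,M,12,0.4,14.7,0.081
muac,M,18,0.3,14.9,0.082
muac,M,24,0.2,15.1,0.083
muac,F,3,0.7,13.0,0.085
muac,F,6,0.6,13.8,0.084
muac,F,9,0.5,14.2,0.083
muac,F,12,0.4,14.4,0.083
muac,F,18,0.3,14.7,0.084
muac,F,24,0.2,14.9,0.085
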