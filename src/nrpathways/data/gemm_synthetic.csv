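age_group,theta,theta_se,alpha,mu,upsilon
25-29,0.1585,0.0190,1.6,15.5,36.8
30-34,0.1577,0.0184,1.6,15.5,36.8
35-39,0.1570,0.0178,1.6,15.5,36.8
40-44,0.1558,0.0171,1.6,15.5,36.8
45-49,0.1532,0.0163,1.6,15.5,36.8
50-54,0.1499,0.0155,1.6,15.5,36.8
55-59,0.1462,0.0146,1.6,15.5,36.8
60-64,0.1421,0.0136,1.6,15.5,36.8
65-69,0.1374,0.0125,1.6,15.5,36.8
70-74,0.1319,0.0113,1.6,15.5,36.8
75-79,0.1253,0.0100,1.6,15.5,36.8
80+,0.1141,0.0085,1.6,15.5,36.8
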