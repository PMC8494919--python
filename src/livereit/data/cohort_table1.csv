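subject,bmi,eit_mean,eit_sd,pdff,injection_current,excluded,exclusion_reason
1,34.4,0.3518,0.0192,2.14,1,0,
2,49.7,0.3290,0.0122,4.05,1,0,
3,39.0,0.3296,0.0130,3.82,2,0,
4,33.0,0.3819,0.0224,27.89,3,1,electrode malfunction
5,30.6,0.3377,0.0211,10.51,2,0,
6,36.3,0.3444,0.0322,4.14,2,0,
7,29.3,0.3280,0.0288,2.41,3,0,
8,37.8,0.3405,0.0134,2.25,3,0,
9,32.0,0.3381,0.0170,6.53,2,0,
10,34.3,0.3007,0.0167,16.44,2,0,
11,27.9,0.3473,0.0168,3.62,2,0,
12,46.8,0.3307,0.0113,5.14,2,0,
13,38.9,0.3305,0.0160,3.31,3,0,
14,25.5,0.3010,0.0160,2.11,2,1,renal failure
15,33.7,0.3306,0.0127,10.78,2,0,
16,27.4,0.3407,0.0267,1.08,3,0,
17,27.1,0.3243,0.0125,6.20,3,0,
18,46.9,0.3455,0.0149,18.56,2,1,leukemia
19,29.8,0.3507,0.0189,2.29,2,0,
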