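subject,sex,bmi,age,waist,height,weight,excluded,exclusion_reason
1,M,34.4,41,116,175,105.2,0,
2,F,49.7,67,131,158.5,124.7,0,
3,F,39.0,63,123.5,160,99.8,0,
4,F,33.0,35,116.5,168.9,94.1,1,electrode malfunction
5,F,30.6,61,92.5,155.5,73.9,0,
6,F,36.3,27,103.5,163.5,97.2,0,
7,F,29.3,42,91,155,70.3,0,
8,F,37.8,60,115.5,174,114.5,0,
9,F,32.0,36,113,170,92.5,0,
10,F,34.3,36,101.5,152,79.2,0,
11,M,27.9,47,95,178,88.5,0,
12,F,46.8,39,130,160,119.8,0,
13,F,38.9,48,114,168,109.9,0,
14,F,25.5,74,96,163.5,68.2,1,renal failure
15,F,33.7,26,95,153,78.9,0,
16,F,27.4,33,93.5,170.5,79.8,0,
17,M,27.1,47,103,178,85.7,0,
18,M,46.9,57,141.5,177.5,147.7,1,leukemia
19,F,29.8,30,102,180.3,96.9,0,
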