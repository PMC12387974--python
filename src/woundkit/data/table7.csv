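patient,ai_slough_pct,ai_necrosis_pct,plan_slough_pct,plan_necrosis_pct
1,59.23,18.85,70.09,20.77
1,58.36,16.86,62.77,27.10
1,60.07,15.99,76.19,15.78
2,70.08,0.37,80.35,3.61
2,69.56,0.45,91.10,3.15
3,66.64,0.00,83.46,0.00
3,68.08,0.00,87.73,0.00
4,32.15,28.99,39.17,51.14
4,30.55,28.57,54.35,37.73
5,10.73,0.00,23.65,0.00
5,10.72,0.00,27.49,0.00
6,33.29,0,33.6,0
6,32.34,0,32.41,0
7,39.48,31.65,36.1,42.01
7,38.03,32.79,32.88,45.94
8,51.87,0.87,50.81,3.14
8,51.67,0.35,49.89,3.38
9,4.46,64.4,7.22,74.7
9,6.07,62.16,6,67.09
10,30.19,0,55.58,0
10,27.54,0,53.74,0
11,0,0,0,0
11,0,0,0,0
12,20.44,0,35.44,0
12,18.99,0,36.36,0
13,18.61,11.29,51.64,17.26
13,20.98,8.51,46.27,23.33
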