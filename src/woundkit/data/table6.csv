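patient,ai_slough_pct,ai_necrosis_pct,plan_slough_pct,plan_necrosis_pct,printed_agreement_slough,printed_agreement_necrosis
1,32.15,28.99,39.17,51.14,0.82,0.57
2,59.23,18.85,70.09,20.77,0.85,0.91
3,41.28,1.43,50.95,2.69,0.81,0.53
5,66.64,0.00,83.46,0.00,0.80,1.00
7,34.94,0.00,39.68,0.00,0.88,1.00
8,52.52,0.03,46.28,8.17,0.87,0.00
9,32.34,0.00,33.60,0.00,0.96,1.00
10,58.36,16.86,62.77,27.10,0.93,0.62
11,19.48,0.62,31.96,0.00,0.61,1.00
12,39.85,52.61,14.20,66.50,0.81,0.79
13,30.03,0.00,24.07,0.00,0.75,1.00
14,38.03,32.79,36.10,42.01,0.95,0.78
15,51.67,0.35,50.81,3.14,0.98,0.11
17,20.20,21.63,28.01,46.42,0.72,0.47
18,6.07,62.16,7.22,74.70,0.84,0.83
19,31.58,7.61,43.57,11.12,0.72,0.68
20,68.39,0.00,77.79,0.00,0.88,1.00
22,60.07,15.99,76.19,15.78,0.79,0.99
24,20.47,23.21,71.73,4.51,0.29,3.15
25,47.98,41.48,17.07,80.31,0.81,0.52
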