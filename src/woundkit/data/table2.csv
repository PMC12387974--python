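patient,device_cm2,reference_cm2,reference2_cm2
1,5.45,5.66,5.68
2,6.51,6.37,6.48
3,8.5,8.66,8.53
4,3.83,3.85,4.14
5,7.91,8.21,8.6
6,14.5,14.33,14.52
7,0.31,0.27,0.33
8,13.65,14.58,14.29
9,1.95,1.99,2.13
10,27.25,27.79,28.41
11,12.5,12.37,12.79
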