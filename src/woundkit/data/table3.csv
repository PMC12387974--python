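patient,measure1_cm2,measure2_cm2
1,7.98,8.58
2,1.79,2.16
3,4.66,4.6
4,15.72,15.32
5,11.51,11.25
6,1.78,1.51
7,11.85,12.11
8,1.99,2.25
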