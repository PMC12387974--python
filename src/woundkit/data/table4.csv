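patient,device1_mm,device2_mm,probe_mm,sentinel
1,4,4,3,0
2,,,2,1
3,5,4,3,0
4,,,0.2,1
6,,,1.2,1
7,,,2,1
8,,,0,1
9,-5,-4,-4,0
10,-4,-6,-4,0
11,20,20,22,0
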