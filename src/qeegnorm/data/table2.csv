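patient,sex,vineland_abc,gmfcs,macs,cfcs,eeg_severity_rank
1,M,46,5,4,5,2
2,M,44,5,5,5,7
3,M,27,5,5,5,8
4,M,35,5,5,5,3
5,M,38,5,4,5,6
6,F,58,2,3,4,1
7,M,60,1,2,1,4
8,M,56,2,4,3,1
9,M,53,2,4,4,7
10,F,77,1,1,1,5
11,F,96,1,1,2,1
12,F,60,1,1,2,5
13,M,101,1,1,2,1
14,F,46,5,5,4,8
15,F,22,5,5,5,6
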