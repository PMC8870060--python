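patient,initial_wrs,snr_db,P1,P2,P3,P4,C1,C2,C3,C4,C5,C6,C7,C8,C9,selected,final_wrs
1,4,10,6,8,6,6,8,6,9,6,7,7,7,6,7,C3,9
2,5,5,7,6,10,9,4,6,10,9,,,,,,P3,6.5
3,4,10,6,4,5,5,5,5,6,8,7,8,8,8,6,C4,7.5
4,4,0,5,3,5,6,6,4,,,,,,,,C1,6
5,4,-7,4,4,5,8,6,7,6,5,5,9,7,6,8,C6,8
6,5,10,0,2,4,5,2,3,4,5,6,5,4,0,5,C5,5
7,3,5,4,7,6,7,5,7,9,6,8,4,7,6,7,C3,7.5
8,5.5,5,7,5,6,7,4,5,5,7,5,6,7,6,6,C7,7.5
9,5,10,4,6,8,5,5,6,6,7,8,7,7,6,5,P3,7.5
10,3,10,2,4,2,3,5,4,5,3,5,4,3,4,9,C9,2
11,6,10,6,9,7,5,5,6,8,6,8,8,8,9,6,C8,8
12,6,-5,5,4,3,5,7,6,7,4,4,7,4,5,8,C9,7
13,3,0,6,2,5,5,4,7,6,2,6,7,4,6,8,C9,7
14,3,0,4,8,6,2,4,3,6,2,4,3,6,5,5,P2,8
15,4,-5,5,2,4,6,8,4,3,7,5,4,1,4,4,C1,7
16,4,-10,5,4,1,2,3,4,6,4,5,4,2,3,5,C3,7
17,5,-5,3,5,8,3,4,4,5,1,3,7,3,3,2,P3,7
18,4,-5,4,6,2,5,2,2,3,5,1,5,5,4,5,P2,7
19,3,-5,3,5,4,4,8,4,3,5,5,4,3,5,5,C1,6
20,5,-10,1,1,1,1,7,7,4,5,5,7,5,6,5,C2,5
21,4,0,2,5,2,2,3,4,4,2,3,2,5,5,4,C8,3
22,3,0,7,3,5,5,6,5,4,4,4,2,2,6,6,P1,7
23,3,10,4,2,4,2,1,3,7,8,2,4,5,1,4,C4,7
24,5,0,3,5,7,3,3,2,4,3,4,6,7,3,2,C7,6
25,5,0,4,1,3,4,5,4,3,3,6,4,4,1,1,C5,3
26,3,0,4,3,5,4,2,6,6,4,3,2,4,7,4,C8,6
27,4,-5,2,3,3,4,5,3,3,6,4,1,4,5,5,C4,7
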