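group_id,average_intake,current_concentration
1,27.75,0.00056
2,5.84,0.00233
3,17.42,0.0012
4,8.92,0.00041
5,7.73,0.0
6,13.73,0.0
7,7.69,0.00538
8,6.03,0.07719
9,11.13,0.00188
10,13.03,0.04704
11,3.95,0.00506
12,5.84,0.0
13,262.9,0.0
14,3.34,0.0
17,8.66,0.0
25,59.96,0.0
26,54.63,0.0
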