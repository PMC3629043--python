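sample,thb_um,bc_um,mean_musp_cm1
1,10.7,7.5,4.1
2,18.1,21.7,5.3
3,32.7,18.6,11.5
4,59.3,21.0,8.0
5,97.9,16.6,4.4
6,55.7,7.0,3.9
7,49.6,11.3,9.2
8,32.8,17.5,6.3
9,73.1,26.0,8.8
10,95.9,37.6,8.4
11,24.2,13.6,3.7
12,22.3,29.3,4.8
13,40.3,31.3,6.5
14,91.1,15.8,8.9
15,11.5,30.8,11.9
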