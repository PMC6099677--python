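id,ec50_uM,pec50
1,0.29,6.538
2,0.18,6.745
3,0.28,6.553
4,0.25,6.602
5,0.33,6.481
6,0.28,6.553
7,2.50,5.602
8,9.60,5.018
9,0.65,6.187
10,0.18,6.745
11,0.14,6.854
12,0.13,6.886
13,0.27,6.569
14,0.19,6.721
15,0.26,6.585
16,0.062,7.208
17,0.28,6.553
18,0.50,6.301
19,2.0,5.699
20,12.0,4.921
21,130,3.886
22,9.30,5.032
23,1.90,5.721
24,0.44,6.357
25,1.40,5.854
26,0.47,6.328
27,0.51,6.292
28,0.40,6.398
29,0.27,6.569
30,0.28,6.553
31,0.34,6.469
32,0.10,7.000
33,0.10,7.000
34,0.27,6.569
35,0.16,6.796
36,0.20,6.699
37,0.23,6.638
38,0.23,6.638
39,0.17,6.770
40,0.32,6.495
41,0.65,6.187
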