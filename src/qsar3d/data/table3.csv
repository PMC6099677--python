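id,experimental_pec50,comfa_pred,comfa_residual,comsia_pred,comsia_residual,is_test,comfa_outlier,comsia_outlier
1,6.538,6.263,0.27,6.435,0.10,1,0,0
2,6.745,6.760,-0.02,6.743,0.00,0,0,0
3,6.553,6.532,0.02,6.552,0.00,0,0,0
4,6.602,6.610,-0.01,6.596,0.01,0,0,0
5,6.482,6.494,-0.01,6.496,-0.01,0,0,0
6,6.553,6.811,-0.26,6.444,0.11,1,0,0
7,5.602,5.559,0.04,5.635,-0.03,0,0,0
8,5.018,4.969,0.05,4.646,0.37,1,0,0
9,6.187,6.205,-0.02,6.197,-0.01,0,0,0
10,6.745,6.761,-0.02,6.651,0.09,1,0,0
11,6.854,7.136,-0.28,6.830,0.02,1,0,0
12,6.886,6.893,-0.01,6.965,-0.08,0,0,0
13,6.569,6.667,-0.10,6.721,-0.15,0,0,0
14,6.721,6.707,0.01,6.826,-0.10,1,0,0
15,6.585,6.601,-0.02,6.569,0.02,0,0,0
16,7.208,7.144,0.06,6.953,0.26,0,0,0
17,6.553,6.530,0.02,6.632,-0.08,0,0,0
18,6.301,5.853,0.45,6.601,-0.30,1,1,0
19,5.699,5.636,0.06,5.613,0.09,0,0,0
20,4.921,5.049,-0.13,4.908,0.01,0,0,0
21,3.886,3.794,0.09,3.894,-0.01,0,0,0
22,5.032,5.157,-0.13,4.980,0.05,0,0,0
23,5.721,6.157,-0.44,5.908,-0.19,1,1,0
24,6.357,6.362,-0.01,6.549,-0.19,0,0,0
25,5.854,5.818,0.04,5.979,-0.13,0,0,0
26,6.328,6.331,0.00,6.345,-0.02,0,0,0
27,6.292,6.269,0.02,6.303,-0.01,0,0,0
28,6.398,6.288,0.11,6.404,-0.01,0,0,0
29,6.569,6.604,-0.04,6.605,-0.04,0,0,0
30,6.553,6.601,-0.05,6.534,0.02,0,0,0
31,6.469,6.539,-0.07,6.403,0.07,0,0,0
32,7.000,6.984,0.02,6.964,0.04,0,0,0
33,7.000,6.921,0.08,6.904,0.10,0,0,0
34,6.569,6.244,0.32,6.539,0.03,1,0,0
35,6.796,6.835,-0.04,6.710,0.09,0,0,0
36,6.699,6.696,0.00,6.572,0.13,0,0,0
37,6.638,6.503,0.14,6.448,0.19,1,0,0
38,6.638,6.570,0.07,6.601,0.04,0,0,0
39,6.770,6.781,-0.01,6.902,-0.13,0,0,0
40,6.495,6.678,-0.18,6.910,-0.42,1,0,1
41,6.187,6.390,-0.20,6.718,-0.53,1,0,1
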