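model,q2,n_components,sep,see,r2_ncv,f,r2_test,contrib_S,contrib_E,contrib_H,contrib_D,contrib_A
CoMFA-SE,0.537,6,0.544,0.067,0.993,525.4,0.865,0.412,0.588,,,
CoMSIA-SE,0.566,7,0.539,0.101,0.985,193.0,0.002,0.299,0.701,,,
CoMSIA-SEHA,0.674,6,0.456,0.119,0.978,161.3,0.790,0.174,0.335,0.215,,0.276
CoMSIA-SEA,0.651,5,0.462,0.151,0.963,118.7,0.760,0.245,0.395,,,0.360
CoMSIA-SEDA,0.601,7,0.517,0.103,0.984,185.5,0.816,0.229,0.324,,0.190,0.257
CoMSIA-SD,0.551,6,0.536,0.217,0.926,46.2,0.347,0.470,,,0.530,
CoMSIA-SHD,0.561,9,0.570,0.095,0.988,172.1,0.237,0.312,,0.398,0.289,
CoMSIA-EHA,0.598,6,0.507,0.136,0.971,123.0,0.765,,0.427,0.299,,0.274
CoMSIA-EHDA,0.508,7,0.574,0.111,0.982,160.3,0.716,,0.375,0.261,0.156,0.208
CoMSIA-ALL,0.669,6,0.460,0.101,0.984,225.9,0.918,0.165,0.279,0.181,0.159,0.215
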