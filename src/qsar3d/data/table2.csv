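condition,parameter,threshold,comfa,comsia
1,q2,> 0.5,0.537,0.669
2,r2,> 0.6,0.865,0.918
3a,r0_sq,close to r2,0.864,0.911
3b,r0_prime_sq,close to r2,0.834,0.885
4a,k,0.85..1.15,1.002,0.996
4b,k_prime,0.85..1.15,0.937,1.004
5a,(r2-r0_sq)/r2,< 0.1,0.001,0.007
5b,(r2-r0_prime_sq)/r2,< 0.1,0.036,0.034
6,|r0_sq-r0_prime_sq|,< 0.3,0.031,0.027
7,rm2,> 0.5,0.793,0.843
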