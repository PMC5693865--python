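name,n_l0,n_e,f_dr,sigma_l,r0,r1,r2,eps0,eps1,eps2,q10,b,c,has_globresp
broadleaf_tree,0.0369,0.0008,0.015,0.0506,1.7560,0.2061,0.0402,0.2180,0.0023,0.0096,2.0,0.1012,-0.0005,true
needleleaf_tree,0.0235,0.0008,0.015,0.112,1.4995,0.2061,0.0402,0.1793,0.0023,0.0096,2.0,0.1012,-0.0005,true
shrub,0.0349,0.0008,0.015,0.0512,2.0749,0.2061,0.0402,0.0774,0.0023,0.0096,2.0,0.1012,-0.0005,true
c3_grass,0.0480,0.0008,0.015,0.0248,2.1956,0.2061,0.0402,0.1408,0.0023,0.0096,2.0,0.1012,-0.0005,true
c4_grass,0.0238,0.0004,0.025,0.0656,,,,,,,2.0,0.1012,-0.0005,false
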