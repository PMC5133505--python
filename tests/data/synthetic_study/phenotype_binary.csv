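sample_id,phenotype,age,sex
S0000,0,57.1662,1
S0001,1,61.881,1
S0002,0,28.8074,1
S0003,0,45.2385,0
S0004,1,44.0457,0
S0005,1,58.2683,1
S0006,0,57.8997,0
S0007,0,59.3925,0
S0008,0,46.8974,1
S0009,1,45.3653,1
S0010,1,54.2755,0
S0011,0,46.9761,0
S0012,0,43.1528,1
S0013,0,54.2787,1
S0014,0,42.9696,1
S0015,0,33.5536,1
S0016,0,34.0784,0
S0017,1,54.9323,0
S0018,0,49.851,1
S0019,0,49.488,1
S0020,1,55.3981,1
S0021,0,73.3213,0
S0022,0,51.0349,0
S0023,1,68.7474,0
S0024,0,62.0376,0
S0025,0,60.0396,0
S0026,0,48.8183,0
S0027,1,61.7383,0
S0028,0,48.9129,0
S0029,0,40.9332,0
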