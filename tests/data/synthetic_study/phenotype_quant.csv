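sample_id,phenotype,age,sex
S0000,0.031400377051721454,57.1662,1
S0001,1.070093936367881,61.881,1
S0002,-0.9600476670785384,28.8074,1
S0003,-0.5423204774241882,45.2385,0
S0004,2.4467508968689713,44.0457,0
S0005,0.9539883503323883,58.2683,1
S0006,-0.5305941560126327,57.8997,0
S0007,-0.4063438268359632,59.3925,0
S0008,-0.7215089139042499,46.8974,1
S0009,1.8499864284427423,45.3653,1
S0010,1.2976843515519612,54.2755,0
S0011,0.4688357657116974,46.9761,0
S0012,-0.5958501278129076,43.1528,1
S0013,0.8560641383130744,54.2787,1
S0014,-0.4555737995243725,42.9696,1
S0015,-0.7459864159593503,33.5536,1
S0016,-1.7782372855663198,34.0784,0
S0017,1.4109036273150901,54.9323,0
S0018,-0.4457257791605385,49.851,1
S0019,0.5735275980314104,49.488,1
S0020,1.7151906986981673,55.3981,1
S0021,0.23569030056258827,73.3213,0
S0022,0.021015387569484803,51.0349,0
S0023,2.1572566488606713,68.7474,0
S0024,0.7781222362954822,62.0376,0
S0025,-0.33138069048276964,60.0396,0
S0026,-0.10232902136871896,48.8183,0
S0027,1.849412222910961,61.7383,0
S0028,-0.7396524836420258,48.9129,0
S0029,-0.6171003208352642,40.9332,0
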