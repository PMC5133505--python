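gene_id	causal	beta_g	beta_t	gamma
GENE0000	True	0.15	0.15	0.5
GENE0001	True	0.15	0.15	0.5
GENE0002	False	0.0	0.0	0.0
GENE0003	False	0.0	0.0	0.0
GENE0004	False	0.0	0.0	0.0
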