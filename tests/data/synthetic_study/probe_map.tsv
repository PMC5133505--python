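gene_id	probe_id
GENE0000	PROBE0000
GENE0001	PROBE0001
GENE0002	PROBE0002
GENE0003	PROBE0003
GENE0004	PROBE0004
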