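1	99999	111105	GENE0000
1	299999	326632	GENE0001
1	499999	524628	GENE0002
1	699999	728569	GENE0003
1	899999	937453	GENE0004
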