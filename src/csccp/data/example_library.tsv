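scaffold_id	position_set_id	position_index	sidechain_id	smiles	mw	prob
S1	PS1	1	p1c1		15	0.2
S1	PS1	1	p1c2		17	0.8
S1	PS1	2	p2c1		17	0.8
S1	PS1	2	p2c2		62	0.2
S1	PS1	3	p3c1		17	0.2
S1	PS1	3	p3c2		62	0.8
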