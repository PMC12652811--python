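#node1	node2	combined_score
CYP3A4	CYP2E1	0.991
CYP3A4	CYP2C8	0.973
CYP3A4	CYP26A1	0.944
CYP3A4	ADH4	0.559
CYP3A4	ADH1A	0.491
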