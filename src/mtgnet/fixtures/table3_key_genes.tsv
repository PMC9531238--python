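name	type	log2fc	p_value	z_score
Plec	gene	-3.5300	0.006660	0.775000
Col1a1	gene	-2.0100	0.000001	1.680000
Pxn	gene	-1.9300	0.001040	1.280000
Serpine1	gene	-1.4300	0.034000	0.732000
Tpm1	gene	4.8400	0.041300	0.756000
Nedd4l	gene	3.8700	0.002240	0.940000
Trip12	gene	2.5500	0.000124	0.578000
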