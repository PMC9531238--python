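name	mature_sequence	log2fc	p_value	homology
miR-21-5p	UAGCUUAUCAGACUGAUGUUGA	-2.2700	0.017800	rat;mouse;human
miR-511-3p	AAUGUGUAGCAAAAGACAGGA	-1.7300	0.003990	rat;mouse;human
miR-145-5p	GUCCAGUUUUCCCAGGAAUCCCU	-1.5300	0.030800	rat;mouse;human
miR-10b-5p	CCCUGUAGAACCGAAUUUGUGU	-1.4600	0.056800	rat;mouse;human
miR-143-3p	UGAGAUGAAGCACUGUAGCUCA	-1.4100	0.001360	rat;mouse;human
miR-214-3p	ACAGCAGGCACAGACAGGCAG	-1.2800	0.001750	rat;mouse;human
miR-764-3p	GAGGAGGCCAUAGUGGCAACUGU	-1.2700	0.002600	rat;mouse
miR-10a-5p	UACCCUGUAGAUCCGAAUUUGUG	-1.0600	0.000464	rat;mouse;human
miR-223-3p	UGUCAGUUUGUCAAAUACCCC	-1.0500	0.010400	rat;mouse;human
miR-155-5p	UUAAUGCUAAUUGUGAUAGGGGU	-1.0400	0.005740	rat;mouse;human
miR-122-5p	UGGAGUGUGACAAUGGUGUUUG	4.0500	0.011800	rat;mouse;human
miR-5132-5p	CGUGGGGCGGUGGACCCAGGCU	1.4200	0.015700	rat;mouse
miR-802-5p	UCAGUAACAAAGAUUCAUCCU	1.1500	0.039800	rat;mouse
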