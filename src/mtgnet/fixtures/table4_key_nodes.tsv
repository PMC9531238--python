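name	type	occurrences	z_score
Mxi1	transcription factor	47100	1.4600
Nfatc4	transcription factor	150000	1.4000
Rxrg	transcription factor	162000	1.3700
Zfp523	transcription factor	64700	1.3600
Foxj2	transcription factor	28700	1.3600
Nkx6-1	transcription factor	35200	0.7900
Klf4	transcription factor	51000	0.6140
Klf5	transcription factor	104000	0.4840
Csrnp1	transcription factor	53600	0.3760
Prdm6	transcription factor	39300	0.3620
miR-5132-5p	miRNA	2.2200	1.4200
miR-764-3p	miRNA	1.6300	1.0700
miR-223-3p	miRNA	0.9200	0.9090
miR-145-5p	miRNA	0.5090	0.8110
miR-122-5p	miRNA	0.7340	0.5950
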