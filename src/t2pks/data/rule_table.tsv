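chemotype	ARO_a	ARO_b	ARO_c	CYC_a	CYC_b	CYC_c	CYC_d	CYC_e	CYC_f	unique
Angucyclines	1	1	0	1	0	0	0	0	0	1
Anthracyclines	1	1	0	0	0	1	0	0	1	1
Anthracyclines	1	1	0	0	0	0	0	0	1	1
Anthracyclines	1	1	0	0	0	1	0	1	0	0
Anthracyclines	1	0	0	0	0	1	0	0	0	1
Benzoisochromanequinones	1	1	0	0	0	0	1	0	0	1
Benzoisochromanequinones	0	1	0	0	0	0	1	0	0	1
PentangularPolyphenols	0	0	1	0	1	0	0	0	0	1
PentangularPolyphenols	0	0	1	1	1	0	0	0	0	0
Tetracenomycins	0	0	1	1	1	0	0	0	0	0
Tetracyclines/AureolicAcids	1	1	0	0	0	1	0	1	0	0
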