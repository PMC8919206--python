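condition	position	gene
embryonic	1	GAPDH
embryonic	2	EF1A
embryonic	3	ACT5C
embryonic	4	NADH
embryonic	5	RPS23
embryonic	6	HSP67
embryonic	7	RPL5
embryonic	8	TBLg2
embryonic	9	TBLb1
embryonic	10	HSP83
embryonic	11	TATA
embryonic	12	18S
sexual	1	EF1A
sexual	2	ACT5C
sexual	3	TBLb1
sexual	4	TBLg2
sexual	5	RPL5
sexual	6	RPS23
sexual	7	NADH
sexual	8	TATA
sexual	9	GAPDH
sexual	10	HSP83
sexual	11	18S
sexual	12	HSP67
worker	1	TATA
worker	2	GAPDH
worker	3	NADH
worker	4	RPS23
worker	5	HSP83
worker	6	EF1A
worker	7	TBLg2
worker	8	HSP67
worker	9	ACT5C
worker	10	TBLb1
worker	11	RPL5
worker	12	18S
adult	1	EF1A
adult	2	ACT5C
adult	3	NADH
adult	4	TBLg2
adult	5	HSP67
adult	6	TBLb1
adult	7	RPS23
adult	8	RPL5
adult	9	GAPDH
adult	10	HSP83
adult	11	TATA
adult	12	18S
tissues	1	HSP67
tissues	2	RPL5
tissues	3	RPS23
tissues	4	NADH
tissues	5	TBLb1
tissues	6	TBLg2
tissues	7	EF1A
tissues	8	HSP83
tissues	9	GAPDH
tissues	10	ACT5C
tissues	11	TATA
tissues	12	18S
injection	1	EF1A
injection	2	TBLg2
injection	3	HSP67
injection	4	ACT5C
injection	5	TBLb1
injection	6	18S
injection	7	RPL5
injection	8	RPS23
injection	9	TATA
injection	10	HSP83
injection	11	GAPDH
injection	12	NADH
starvation	1	TBLg2
starvation	2	HSP67
starvation	3	RPL5
starvation	4	ACT5C
starvation	5	TBLb1
starvation	6	RPS23
starvation	7	HSP83
starvation	8	EF1A
starvation	9	TATA
starvation	10	18S
starvation	11	GAPDH
starvation	12	NADH
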