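condition	gene	rank_genorm	rank_normfinder	rank_bestkeeper	rank_deltact
embryonic	GAPDH	4	1	6	1
embryonic	EF1A	1	5	3	3
embryonic	ACT5C	6	2	7	2
embryonic	NADH	1	7	4	6
embryonic	RPS23	3	6	2	5
embryonic	HSP67	5	3	5	4
embryonic	RPL5	7	10	1	10
embryonic	TBLg2	9	4	9	7
embryonic	TBLb1	8	9	8	9
embryonic	HSP83	10	8	10	8
embryonic	TATA	11	11	11	11
embryonic	18S	12	12	12	12
sexual	EF1A	1	4	2	2
sexual	ACT5C	3	1	7	1
sexual	TBLb1	1	3	5	3
sexual	TBLg2	4	2	6	4
sexual	RPL5	5	8	3	5
sexual	RPS23	7	10	1	10
sexual	NADH	8	6	4	8
sexual	TATA	6	7	8	7
sexual	GAPDH	9	5	10	6
sexual	HSP83	10	9	11	9
sexual	18S	11	11	9	11
sexual	HSP67	12	12	12	12
worker	TATA	5	2	2	1
worker	GAPDH	3	1	4	2
worker	NADH	1	5	8	3
worker	RPS23	7	3	1	6
worker	HSP83	1	7	6	5
worker	EF1A	8	4	9	4
worker	TBLg2	6	6	5	8
worker	HSP67	4	8	7	7
worker	ACT5C	11	10	3	10
worker	TBLb1	9	9	10	9
worker	RPL5	10	11	11	11
worker	18S	12	12	12	12
adult	EF1A	4	1	7	1
adult	ACT5C	1	3	6	2
adult	NADH	1	5	5	5
adult	TBLg2	3	6	2	4
adult	HSP67	5	4	3	3
adult	TBLb1	6	2	9	6
adult	RPS23	7	10	1	10
adult	RPL5	8	9	4	9
adult	GAPDH	9	7	8	7
adult	HSP83	10	8	10	8
adult	TATA	11	11	11	11
adult	18S	12	12	12	12
tissues	HSP67	3	1	1	1
tissues	RPL5	1	5	2	4
tissues	RPS23	1	3	5	3
tissues	NADH	5	2	3	2
tissues	TBLb1	4	6	8	5
tissues	TBLg2	8	4	9	6
tissues	EF1A	6	9	4	8
tissues	HSP83	7	7	6	7
tissues	GAPDH	10	8	7	9
tissues	ACT5C	11	10	10	10
tissues	TATA	9	11	11	11
tissues	18S	12	12	12	12
injection	EF1A	1	1	3	1
injection	TBLg2	1	2	2	2
injection	HSP67	3	3	5	4
injection	ACT5C	4	5	9	3
injection	TBLb1	5	4	8	5
injection	18S	11	11	1	11
injection	RPL5	6	6	7	6
injection	RPS23	9	9	4	9
injection	TATA	7	8	12	7
injection	HSP83	8	7	11	8
injection	GAPDH	10	10	10	10
injection	NADH	12	12	6	12
starvation	TBLg2	1	1	3	1
starvation	HSP67	1	4	1	3
starvation	RPL5	5	2	9	2
starvation	ACT5C	4	5	4	4
starvation	TBLb1	3	6	4	6
starvation	RPS23	9	7	2	7
starvation	HSP83	6	3	10	5
starvation	EF1A	7	8	7	8
starvation	TATA	8	9	6	9
starvation	18S	10	10	8	10
starvation	GAPDH	11	11	11	11
starvation	NADH	12	12	12	12
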