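motif	chicken_promoter	duck_promoter	zebra_finch_promoter	mouse_promoter	human_promoter	chicken_genome
AC	405	433	378	6006	3189	97994
AT	276	294	270	739	887	52845
AG	174	174	186	2572	1356	98988
AGG	131	98	170	426	192	13509
AAT	68	61	40	264	413	18974
CCG	66	1	87	200	462	722
AAC	46	38	16	356	283	13218
AGC	40	26	72	73	67	31737
AAAT	30	49	21	432	393	6017
AAAG	26	21	10	583	223	2769
CG	26	0	36	177	207	687
ATCCC	18	6	14	1	0	
AAAC	17	33	14	563	183	6290
AAGG	15	11	13	274	122	1094
AAG	13	9	5	246	75	15000
ACC	13	8	8	150	224	8154
AGAGG	13	5	7	54	0	
ATCC	12	5	32	41	29	436
ACGGC	12	0	12	0	0	
AAGGG	11	22	6	23	4	
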