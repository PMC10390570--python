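name	segment_class	ordinal	orientation	cluster	rss_5p	rss_3p	functionality
TRBV1	V	1	forward	none	none	spacer23	P
TRBV2	V	2	forward	none	none	spacer23	F
TRBV3-1	V	3	forward	none	none	spacer23	F
TRBV4-1	V	4	forward	none	none	spacer23	F
TRBV5-1	V	5	forward	none	none	spacer23	F
TRBV6-1	V	6	forward	none	none	spacer23	F
TRBV7-1	V	7	forward	none	none	spacer23	P
TRBV4-2	V	8	forward	none	none	spacer23	F
TRBV6-2	V	9	forward	none	none	spacer23	F
TRBV3-2	V	10	forward	none	none	spacer23	P
TRBV4-3	V	11	forward	none	none	spacer23	F
TRBV6-3	V	12	forward	none	none	spacer23	F
TRBV7-2	V	13	forward	none	none	spacer23	F
TRBV8-1	V	14	forward	none	none	spacer23	P
TRBV5-2	V	15	forward	none	none	spacer23	P
TRBV6-4	V	16	forward	none	none	spacer23	F
TRBV7-3	V	17	forward	none	none	spacer23	F
TRBV8-2	V	18	forward	none	none	spacer23	P
TRBV5-3	V	19	forward	none	none	spacer23	P
TRBV9	V	20	forward	none	none	spacer23	F
TRBV10-1	V	21	forward	none	none	spacer23	F
TRBV11-1	V	22	forward	none	none	spacer23	F
TRBV12-1	V	23	forward	none	none	spacer23	P
TRBV10-2	V	24	forward	none	none	spacer23	F
TRBV11-2	V	25	forward	none	none	spacer23	F
TRBV12-2	V	26	forward	none	none	spacer23	P
TRBV6-5	V	27	forward	none	none	spacer23	F
TRBV7-4	V	28	forward	none	none	spacer23	F
TRBV5-4	V	29	forward	none	none	spacer23	F
TRBV6-6	V	30	forward	none	none	spacer23	F
TRBV7-5	V	31	forward	none	none	spacer23	P
TRBV5-5	V	32	forward	none	none	spacer23	F
TRBV6-7	V	33	forward	none	none	spacer23	P
TRBV7-6	V	34	forward	none	none	spacer23	F
TRBV5-6	V	35	forward	none	none	spacer23	F
TRBV6-8	V	36	forward	none	none	spacer23	F
TRBV7-7	V	37	forward	none	none	spacer23	F
TRBV5-7	V	38	forward	none	none	spacer23	ORF
TRBV6-9	V	39	forward	none	none	spacer23	F
TRBV7-8	V	40	forward	none	none	spacer23	F
TRBV5-8	V	41	forward	none	none	spacer23	F
TRBV7-9	V	42	forward	none	none	spacer23	F
TRBV13	V	43	forward	none	none	spacer23	F
TRBV10-3	V	44	forward	none	none	spacer23	F
TRBV11-3	V	45	forward	none	none	spacer23	F
TRBV12-3	V	46	forward	none	none	spacer23	F
TRBV12-4	V	47	forward	none	none	spacer23	F
TRBV12-5	V	48	forward	none	none	spacer23	F
TRBV14	V	49	forward	none	none	spacer23	F
TRBV15	V	50	forward	none	none	spacer23	F
TRBV16	V	51	forward	none	none	spacer23	F
TRBV17	V	52	forward	none	none	spacer23	ORF
TRBV18	V	53	forward	none	none	spacer23	F
TRBV19	V	54	forward	none	none	spacer23	F
TRBV20-1	V	55	forward	none	none	spacer23	F
TRBV21-1	V	56	forward	none	none	spacer23	P
TRBV22-1	V	57	forward	none	none	spacer23	P
TRBV23-1	V	58	forward	none	none	spacer23	ORF
TRBV24-1	V	59	forward	none	none	spacer23	F
TRBV25-1	V	60	forward	none	none	spacer23	F
TRBV26	V	61	forward	none	none	spacer23	P
TRBV27	V	62	forward	none	none	spacer23	F
TRBV28	V	63	forward	none	none	spacer23	F
TRBV29-1	V	64	forward	none	none	spacer23	F
TRBD1	D	65	forward	DJC1	spacer12	spacer23	F
TRBJ1-1	J	66	forward	DJC1	spacer12	none	F
TRBJ1-2	J	67	forward	DJC1	spacer12	none	F
TRBJ1-3	J	68	forward	DJC1	spacer12	none	F
TRBJ1-4	J	69	forward	DJC1	spacer12	none	F
TRBJ1-5	J	70	forward	DJC1	spacer12	none	F
TRBJ1-6	J	71	forward	DJC1	spacer12	none	F
TRBC1	C	72	forward	DJC1	none	none	F
TRBD2	D	73	forward	DJC2	spacer12	spacer23	F
TRBJ2-1	J	74	forward	DJC2	spacer12	none	F
TRBJ2-2	J	75	forward	DJC2	spacer12	none	F
TRBJ2-3	J	76	forward	DJC2	spacer12	none	F
TRBJ2-4	J	77	forward	DJC2	spacer12	none	F
TRBJ2-5	J	78	forward	DJC2	spacer12	none	F
TRBJ2-6	J	79	forward	DJC2	spacer12	none	F
TRBJ2-7	J	80	forward	DJC2	spacer12	none	F
TRBC2	C	81	forward	DJC2	none	none	F
TRBV30	V	82	reverse	none	none	spacer23	F
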