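name	segment_class	ordinal	orientation	cluster	rss_5p	rss_3p	functionality
TRBV1	V	1	forward	none	none	spacer23	F
TRBV2	V	2	forward	none	none	spacer23	F
TRBV3	V	3	forward	none	none	spacer23	F
TRBV4	V	4	forward	none	none	spacer23	F
TRBV5	V	5	forward	none	none	spacer23	F
TRBV6	V	6	forward	none	none	spacer23	P
TRBV7	V	7	forward	none	none	spacer23	P
TRBV8	V	8	forward	none	none	spacer23	P
TRBV9	V	9	forward	none	none	spacer23	P
TRBV10	V	10	forward	none	none	spacer23	P
TRBV11	V	11	forward	none	none	spacer23	P
TRBV12-1	V	12	forward	none	none	spacer23	F
TRBV12-2	V	13	forward	none	none	spacer23	F
TRBV13-1	V	14	forward	none	none	spacer23	F
TRBV13-2	V	15	forward	none	none	spacer23	F
TRBV13-3	V	16	forward	none	none	spacer23	F
TRBV14	V	17	forward	none	none	spacer23	F
TRBV15	V	18	forward	none	none	spacer23	F
TRBV16	V	19	forward	none	none	spacer23	F
TRBV17	V	20	forward	none	none	spacer23	F
TRBV18	V	21	forward	none	none	spacer23	P
TRBV19	V	22	forward	none	none	spacer23	F
TRBV20	V	23	forward	none	none	spacer23	F
TRBV21	V	24	forward	none	none	spacer23	P
TRBV22	V	25	forward	none	none	spacer23	P
TRBV23	V	26	forward	none	none	spacer23	F
TRBV24	V	27	forward	none	none	spacer23	F
TRBV25	V	28	forward	none	none	spacer23	P
TRBV26	V	29	forward	none	none	spacer23	F
TRBV27	V	30	forward	none	none	spacer23	P
TRBV28	V	31	forward	none	none	spacer23	P
TRBV29	V	32	forward	none	none	spacer23	F
TRBV30	V	33	forward	none	none	spacer23	F
TRBD1	D	34	forward	DJC1	spacer12	spacer23	F
TRBJ1-1	J	35	forward	DJC1	spacer12	none	F
TRBJ1-2	J	36	forward	DJC1	spacer12	none	F
TRBJ1-3	J	37	forward	DJC1	spacer12	none	F
TRBJ1-4	J	38	forward	DJC1	spacer12	none	F
TRBJ1-5	J	39	forward	DJC1	spacer12	none	F
TRBJ1-6	J	40	forward	DJC1	spacer12	none	F
TRBJ1-7	J	41	forward	DJC1	spacer12	none	P
TRBC1	C	42	forward	DJC1	none	none	F
TRBD2	D	43	forward	DJC2	spacer12	spacer23	F
TRBJ2-1	J	44	forward	DJC2	spacer12	none	F
TRBJ2-2	J	45	forward	DJC2	spacer12	none	F
TRBJ2-3	J	46	forward	DJC2	spacer12	none	F
TRBJ2-4	J	47	forward	DJC2	spacer12	none	F
TRBJ2-5	J	48	forward	DJC2	spacer12	none	F
TRBJ2-6	J	49	forward	DJC2	spacer12	none	P
TRBJ2-7	J	50	forward	DJC2	spacer12	none	F
TRBC2	C	51	forward	DJC2	none	none	F
TRBV31	V	52	reverse	none	none	spacer23	F
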