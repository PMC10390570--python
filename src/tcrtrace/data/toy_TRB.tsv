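name	segment_class	ordinal	orientation	cluster	rss_5p	rss_3p	functionality
TOYV1	V	1	forward	none	none	spacer23	F
TOYV2	V	2	forward	none	none	spacer23	F
TOYV3	V	3	forward	none	none	spacer23	F
TOYD1	D	4	forward	DJC1	spacer12	spacer23	F
TOYJ1-1	J	5	forward	DJC1	spacer12	none	F
TOYJ1-2	J	6	forward	DJC1	spacer12	none	F
TOYC1	C	7	forward	DJC1	none	none	F
TOYD2	D	8	forward	DJC2	spacer12	spacer23	F
TOYJ2-1	J	9	forward	DJC2	spacer12	none	F
TOYJ2-2	J	10	forward	DJC2	spacer12	none	F
TOYC2	C	11	forward	DJC2	none	none	F
TOYVR	V	12	reverse	none	none	spacer23	F
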