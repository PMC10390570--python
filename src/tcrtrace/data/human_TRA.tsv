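name	segment_class	ordinal	orientation	cluster	rss_5p	rss_3p	functionality
TRAV1-1	V	1	forward	none	none	spacer23	F
TRAV1-2	V	2	forward	none	none	spacer23	F
TRAV2	V	3	forward	none	none	spacer23	F
TRAV3	V	4	forward	none	none	spacer23	F
TRAV4	V	5	forward	none	none	spacer23	F
TRAV5	V	6	forward	none	none	spacer23	F
TRAV6	V	7	forward	none	none	spacer23	F
TRAV7	V	8	forward	none	none	spacer23	F
TRAV8-1	V	9	forward	none	none	spacer23	F
TRAV9-1	V	10	forward	none	none	spacer23	F
TRAV10	V	11	forward	none	none	spacer23	F
TRAV11	V	12	forward	none	none	spacer23	P
TRAV12-1	V	13	forward	none	none	spacer23	F
TRAV8-2	V	14	forward	none	none	spacer23	F
TRAV8-3	V	15	forward	none	none	spacer23	F
TRAV13-1	V	16	forward	none	none	spacer23	F
TRAV12-2	V	17	forward	none	none	spacer23	F
TRAV8-4	V	18	forward	none	none	spacer23	F
TRAV8-5	V	19	forward	none	none	spacer23	P
TRAV13-2	V	20	forward	none	none	spacer23	F
TRAV14DV4	V	21	forward	none	none	spacer23	F
TRAV9-2	V	22	forward	none	none	spacer23	F
TRAV15	V	23	forward	none	none	spacer23	P
TRAV12-3	V	24	forward	none	none	spacer23	F
TRAV8-6	V	25	forward	none	none	spacer23	F
TRAV16	V	26	forward	none	none	spacer23	F
TRAV17	V	27	forward	none	none	spacer23	F
TRAV18	V	28	forward	none	none	spacer23	F
TRAV19	V	29	forward	none	none	spacer23	F
TRAV20	V	30	forward	none	none	spacer23	F
TRAV21	V	31	forward	none	none	spacer23	F
TRAV22	V	32	forward	none	none	spacer23	F
TRAV23DV6	V	33	forward	none	none	spacer23	F
TRAV24	V	34	forward	none	none	spacer23	F
TRAV25	V	35	forward	none	none	spacer23	F
TRAV26-1	V	36	forward	none	none	spacer23	F
TRAV8-7	V	37	forward	none	none	spacer23	P
TRAV27	V	38	forward	none	none	spacer23	F
TRAV28	V	39	forward	none	none	spacer23	P
TRAV29DV5	V	40	forward	none	none	spacer23	F
TRAV30	V	41	forward	none	none	spacer23	F
TRAV31	V	42	forward	none	none	spacer23	P
TRAV32	V	43	forward	none	none	spacer23	P
TRAV33	V	44	forward	none	none	spacer23	P
TRAV34	V	45	forward	none	none	spacer23	F
TRAV35	V	46	forward	none	none	spacer23	F
TRAV36DV7	V	47	forward	none	none	spacer23	F
TRAV37	V	48	forward	none	none	spacer23	P
TRAV38-1	V	49	forward	none	none	spacer23	F
TRAV38-2DV8	V	50	forward	none	none	spacer23	F
TRAV39	V	51	forward	none	none	spacer23	F
TRAV40	V	52	forward	none	none	spacer23	F
TRAV41	V	53	forward	none	none	spacer23	F
TRAJ61	J	54	forward	none	spacer12	none	P
TRAJ60	J	55	forward	none	spacer12	none	P
TRAJ59	J	56	forward	none	spacer12	none	P
TRAJ58	J	57	forward	none	spacer12	none	ORF
TRAJ57	J	58	forward	none	spacer12	none	F
TRAJ56	J	59	forward	none	spacer12	none	F
TRAJ55	J	60	forward	none	spacer12	none	P
TRAJ54	J	61	forward	none	spacer12	none	F
TRAJ53	J	62	forward	none	spacer12	none	F
TRAJ52	J	63	forward	none	spacer12	none	F
TRAJ51	J	64	forward	none	spacer12	none	P
TRAJ50	J	65	forward	none	spacer12	none	F
TRAJ49	J	66	forward	none	spacer12	none	F
TRAJ48	J	67	forward	none	spacer12	none	F
TRAJ47	J	68	forward	none	spacer12	none	F
TRAJ46	J	69	forward	none	spacer12	none	F
TRAJ45	J	70	forward	none	spacer12	none	F
TRAJ44	J	71	forward	none	spacer12	none	F
TRAJ43	J	72	forward	none	spacer12	none	F
TRAJ42	J	73	forward	none	spacer12	none	F
TRAJ41	J	74	forward	none	spacer12	none	F
TRAJ40	J	75	forward	none	spacer12	none	F
TRAJ39	J	76	forward	none	spacer12	none	F
TRAJ38	J	77	forward	none	spacer12	none	F
TRAJ37	J	78	forward	none	spacer12	none	F
TRAJ36	J	79	forward	none	spacer12	none	F
TRAJ35	J	80	forward	none	spacer12	none	ORF
TRAJ34	J	81	forward	none	spacer12	none	F
TRAJ33	J	82	forward	none	spacer12	none	F
TRAJ32	J	83	forward	none	spacer12	none	F
TRAJ31	J	84	forward	none	spacer12	none	F
TRAJ30	J	85	forward	none	spacer12	none	F
TRAJ29	J	86	forward	none	spacer12	none	F
TRAJ28	J	87	forward	none	spacer12	none	F
TRAJ27	J	88	forward	none	spacer12	none	F
TRAJ26	J	89	forward	none	spacer12	none	F
TRAJ25	J	90	forward	none	spacer12	none	P
TRAJ24	J	91	forward	none	spacer12	none	F
TRAJ23	J	92	forward	none	spacer12	none	F
TRAJ22	J	93	forward	none	spacer12	none	F
TRAJ21	J	94	forward	none	spacer12	none	F
TRAJ20	J	95	forward	none	spacer12	none	F
TRAJ19	J	96	forward	none	spacer12	none	P
TRAJ18	J	97	forward	none	spacer12	none	F
TRAJ17	J	98	forward	none	spacer12	none	F
TRAJ16	J	99	forward	none	spacer12	none	F
TRAJ15	J	100	forward	none	spacer12	none	F
TRAJ14	J	101	forward	none	spacer12	none	F
TRAJ13	J	102	forward	none	spacer12	none	F
TRAJ12	J	103	forward	none	spacer12	none	F
TRAJ11	J	104	forward	none	spacer12	none	F
TRAJ10	J	105	forward	none	spacer12	none	F
TRAJ9	J	106	forward	none	spacer12	none	F
TRAJ8	J	107	forward	none	spacer12	none	F
TRAJ7	J	108	forward	none	spacer12	none	F
TRAJ6	J	109	forward	none	spacer12	none	F
TRAJ5	J	110	forward	none	spacer12	none	F
TRAJ4	J	111	forward	none	spacer12	none	F
TRAJ3	J	112	forward	none	spacer12	none	F
TRAJ2	J	113	forward	none	spacer12	none	P
TRAJ1	J	114	forward	none	spacer12	none	P
TRAC	C	115	forward	none	none	none	F
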