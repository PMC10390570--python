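name	segment_class	ordinal	orientation	cluster	rss_5p	rss_3p	functionality
TRAV1	V	1	forward	none	none	spacer23	F
TRAV2	V	2	forward	none	none	spacer23	F
TRAV3-1	V	3	forward	none	none	spacer23	F
TRAV3-3	V	4	forward	none	none	spacer23	F
TRAV3-4	V	5	forward	none	none	spacer23	F
TRAV4-2	V	6	forward	none	none	spacer23	F
TRAV4-3	V	7	forward	none	none	spacer23	F
TRAV4-4DV10	V	8	forward	none	none	spacer23	F
TRAV5-1	V	9	forward	none	none	spacer23	F
TRAV5-2	V	10	forward	none	none	spacer23	P
TRAV5-4	V	11	forward	none	none	spacer23	F
TRAV6-1	V	12	forward	none	none	spacer23	F
TRAV6-2	V	13	forward	none	none	spacer23	F
TRAV6-3	V	14	forward	none	none	spacer23	F
TRAV6-4	V	15	forward	none	none	spacer23	F
TRAV6-5	V	16	forward	none	none	spacer23	F
TRAV6-6	V	17	forward	none	none	spacer23	F
TRAV6-7DV9	V	18	forward	none	none	spacer23	F
TRAV7-1	V	19	forward	none	none	spacer23	F
TRAV7-2	V	20	forward	none	none	spacer23	F
TRAV7-3	V	21	forward	none	none	spacer23	F
TRAV7-4	V	22	forward	none	none	spacer23	F
TRAV7-5	V	23	forward	none	none	spacer23	F
TRAV7-6	V	24	forward	none	none	spacer23	F
TRAV8-1	V	25	forward	none	none	spacer23	F
TRAV8-2	V	26	forward	none	none	spacer23	F
TRAV9-1	V	27	forward	none	none	spacer23	F
TRAV9-2	V	28	forward	none	none	spacer23	F
TRAV9-3	V	29	forward	none	none	spacer23	F
TRAV9-4	V	30	forward	none	none	spacer23	F
TRAV10	V	31	forward	none	none	spacer23	F
TRAV11	V	32	forward	none	none	spacer23	P
TRAV12-1	V	33	forward	none	none	spacer23	F
TRAV12-2	V	34	forward	none	none	spacer23	F
TRAV12-3	V	35	forward	none	none	spacer23	F
TRAV13-1	V	36	forward	none	none	spacer23	F
TRAV13-2	V	37	forward	none	none	spacer23	F
TRAV13-4DV7	V	38	forward	none	none	spacer23	F
TRAV14-1	V	39	forward	none	none	spacer23	F
TRAV14-2	V	40	forward	none	none	spacer23	F
TRAV14-3	V	41	forward	none	none	spacer23	F
TRAV15-1DV6-1	V	42	forward	none	none	spacer23	F
TRAV15-2DV6-2	V	43	forward	none	none	spacer23	F
TRAV16	V	44	forward	none	none	spacer23	F
TRAV17	V	45	forward	none	none	spacer23	F
TRAV18	V	46	forward	none	none	spacer23	P
TRAV19	V	47	forward	none	none	spacer23	F
TRAV20	V	48	forward	none	none	spacer23	F
TRAV21DV12	V	49	forward	none	none	spacer23	F
TRAJ61	J	50	forward	none	spacer12	none	P
TRAJ60	J	51	forward	none	spacer12	none	P
TRAJ59	J	52	forward	none	spacer12	none	P
TRAJ58	J	53	forward	none	spacer12	none	F
TRAJ57	J	54	forward	none	spacer12	none	F
TRAJ56	J	55	forward	none	spacer12	none	F
TRAJ55	J	56	forward	none	spacer12	none	P
TRAJ54	J	57	forward	none	spacer12	none	F
TRAJ53	J	58	forward	none	spacer12	none	F
TRAJ52	J	59	forward	none	spacer12	none	F
TRAJ51	J	60	forward	none	spacer12	none	P
TRAJ50	J	61	forward	none	spacer12	none	F
TRAJ49	J	62	forward	none	spacer12	none	F
TRAJ48	J	63	forward	none	spacer12	none	F
TRAJ47	J	64	forward	none	spacer12	none	F
TRAJ46	J	65	forward	none	spacer12	none	F
TRAJ45	J	66	forward	none	spacer12	none	F
TRAJ44	J	67	forward	none	spacer12	none	F
TRAJ43	J	68	forward	none	spacer12	none	F
TRAJ42	J	69	forward	none	spacer12	none	F
TRAJ41	J	70	forward	none	spacer12	none	F
TRAJ40	J	71	forward	none	spacer12	none	F
TRAJ39	J	72	forward	none	spacer12	none	F
TRAJ38	J	73	forward	none	spacer12	none	F
TRAJ37	J	74	forward	none	spacer12	none	F
TRAJ36	J	75	forward	none	spacer12	none	F
TRAJ35	J	76	forward	none	spacer12	none	F
TRAJ34	J	77	forward	none	spacer12	none	F
TRAJ33	J	78	forward	none	spacer12	none	F
TRAJ32	J	79	forward	none	spacer12	none	F
TRAJ31	J	80	forward	none	spacer12	none	F
TRAJ30	J	81	forward	none	spacer12	none	F
TRAJ29	J	82	forward	none	spacer12	none	P
TRAJ28	J	83	forward	none	spacer12	none	F
TRAJ27	J	84	forward	none	spacer12	none	F
TRAJ26	J	85	forward	none	spacer12	none	F
TRAJ25	J	86	forward	none	spacer12	none	P
TRAJ24	J	87	forward	none	spacer12	none	F
TRAJ23	J	88	forward	none	spacer12	none	F
TRAJ22	J	89	forward	none	spacer12	none	F
TRAJ21	J	90	forward	none	spacer12	none	F
TRAJ20	J	91	forward	none	spacer12	none	P
TRAJ19	J	92	forward	none	spacer12	none	P
TRAJ18	J	93	forward	none	spacer12	none	F
TRAJ17	J	94	forward	none	spacer12	none	F
TRAJ16	J	95	forward	none	spacer12	none	F
TRAJ15	J	96	forward	none	spacer12	none	F
TRAJ14	J	97	forward	none	spacer12	none	P
TRAJ13	J	98	forward	none	spacer12	none	F
TRAJ12	J	99	forward	none	spacer12	none	F
TRAJ11	J	100	forward	none	spacer12	none	F
TRAJ10	J	101	forward	none	spacer12	none	F
TRAJ9	J	102	forward	none	spacer12	none	F
TRAJ8	J	103	forward	none	spacer12	none	P
TRAJ7	J	104	forward	none	spacer12	none	P
TRAJ6	J	105	forward	none	spacer12	none	F
TRAJ5	J	106	forward	none	spacer12	none	F
TRAJ4	J	107	forward	none	spacer12	none	P
TRAJ3	J	108	forward	none	spacer12	none	P
TRAJ2	J	109	forward	none	spacer12	none	F
TRAJ1	J	110	forward	none	spacer12	none	P
TRAC	C	111	forward	none	none	none	F
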