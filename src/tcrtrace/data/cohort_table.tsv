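group	sample_id	accession	n_cells	n_unique_sequences	n_functional	pct_functional	pct_single	pct_multiple
human_thymus_total	T01	FCAImmP7851883	5208	8596	1668	32.028	85.012	14.988
human_thymus_total	T02	T06_TH_TOT_VDJT_4	9864	22112	5971	60.533	59.940	40.060
human_thymus_total	T03	T03_TH_TOT_VDJT_2	7079	12522	3007	42.478	81.942	18.058
human_thymus_total	T04	FCAImmP7851887	3997	71811	1892	47.336	83.510	16.490
human_thymus_total	T05	FCAImmP8105207	3107	57932	2009	64.660	89.945	10.055
human_thymus_cd45pos	P01	FCAImmP7292943	5457	9362	2170	39.765	82.811	17.189
human_thymus_cd45pos	P02	FCAImmP7292946	5102	9474	2125	41.650	83.576	16.424
human_thymus_cd45pos	P03	FCAImmP7607591	2783	4785	1066	38.304	83.865	16.135
human_thymus_cd45pos	P04	FCAImmP7607599	1736	3000	636	36.636	86.792	13.208
human_thymus_cd45pos	P05	FCAImmP7607608	2468	4493	1050	42.545	83.429	16.571
human_thymus_cd45neg	N01	FCAImmP7607609	1877	2235	91	4.848	89.011	10.989
human_thymus_cd45neg	N02	FCAImmP7607600	844	1190	143	16.943	90.909	9.091
human_blood_frail	R01	GSM4750315	3457	7388	2167	62.684	91.463	8.537
human_blood_frail	R02	GSM4750312	993	2314	712	71.702	93.961	6.039
human_blood_frail	R03	GSM4750313	1102	2412	732	66.425	89.481	10.519
human_blood_frail	R04	GSM4750314	2041	4638	1421	69.623	88.951	11.049
human_blood_frail	R05	GSM4750316	980	2424	719	73.367	92.629	7.371
human_blood_young	C01	GSM4750317	3845	9310	2437	63.381	90.562	9.438
human_blood_young	C02	GSM4750318	4180	9563	2262	54.115	89.920	10.080
human_blood_young	C03	GSM4750319	4740	11575	2941	62.046	89.629	10.371
human_blood_old	L01	GSM5684311	6692	14197	4182	62.493	86.227	13.773
human_blood_old	L02	GSM4750323	3143	6721	2074	65.988	88.042	11.958
human_blood_old	L03	GSM4750325	5277	11824	3431	65.018	87.205	12.795
human_blood_old	L04	GSM5684309	5459	11556	3437	62.960	85.569	14.431
human_blood_old	L05	GSM5684310	6931	14769	4122	59.472	84.619	15.381
mouse_lymph_node	LN1	GSM5172690	10141	22153	7555	74.500	79.616	20.384
mouse_lymph_node	LN2	GSM5172691	10945	23463	7910	72.270	79.897	20.103
mouse_lymph_node	LN3	GSM5172698	4270	8952	2654	62.155	79.502	20.498
mouse_spleen	S1	GSM5172688	15024	30524	9337	62.147	79.502	20.498
mouse_spleen	S2	GSM5172689	9362	20339	6973	74.482	81.171	18.829
mouse_spleen	S3	GSM5172696	7362	15555	5383	73.119	81.629	18.371
mouse_blood	B1	GSM5172686	7177	14709	5063	70.545	82.895	17.105
mouse_blood	B2	GSM5172687	8276	17309	6058	73.200	81.695	18.305
mouse_blood	B3	GSM5172694	3813	7703	2559	67.113	81.595	18.405
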