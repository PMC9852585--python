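rsid	phenotype	gene	chrom	pos	a1	a0	freq1	beta_disc	se_disc	p_disc	beta_repl	se_repl	q_repl
rs4820325	Leg FMR	MAFF/PLA2G6	22	38599978	A	G	0.58	-0.022	0.002	9.61e-23	-0.043	0.011	9.55e-04
rs117068593	Leg FMR	RIN3	14	93118229	T	C	0.19	-0.026	0.003	7.25e-20	-0.024	0.014	0.125
rs1047891	Android LMI	CPS1	2	211540507	A	C	0.32	0.022	0.002	1.31e-19	0.028	0.011	4.65e-02
rs150985439	Android LMI	CYBRD1	2	172417398	C	G	0.25	-0.023	0.003	3.50e-19	0.006	0.012	0.781
rs62218301	Leg FMR	LOC100506403	21	36741262	G	A	0.17	-0.027	0.003	3.69e-19	-0.006	0.014	0.517
rs13072731	Android LMI	ACVR2B/EXOG	3	38533335	C	A	0.61	0.021	0.002	5.15e-19	0.022	0.011	8.34e-02
rs17684944	Leg FMR	NMT1/MIR6784	17	43187141	C	T	0.55	0.02	0.002	9.80e-19	0.013	0.011	0.216
rs2736208	Gynoid fat mass	TRPS1	8	116826244	C	T	0.76	0.023	0.003	9.83e-19	0.003	0.012	0.584
rs11079849	SFI	IGF2BP1	17	47090785	T	C	0.33	-0.02	0.002	2.33e-17	-0.015	0.011	0.216
rs17325374	Android FMI	FBXO36	2	230822858	G	A	0.32	0.02	0.002	3.58e-17	0.033	0.011	1.88e-02
rs3749748	Android LMI	LINC01184	5	127350549	T	C	0.25	0.022	0.003	6.00e-17	-0.001	0.012	0.691
rs12359330	Leg FMR	ADAMTS14	10	72414845	T	C	0.27	0.021	0.003	1.32e-16	0.027	0.012	6.86e-02
rs12451882	Total lean %	UBTF	17	42301922	T	C	0.31	-0.02	0.002	2.06e-16	-0.005	0.011	0.517
rs4527444	Android LMI	PCDH7	4	30842780	G	A	0.54	0.019	0.002	3.20e-16	-0.007	0.011	0.781
rs1504797	Android LMI	MMP16	8	89434405	C	T	0.3	-0.02	0.002	9.00e-16	-0.008	0.012	0.485
rs2881198	Android LMI	LOC730338	7	46634506	C	G	0.54	-0.018	0.002	1.82e-15	-0.019	0.011	0.125
rs10761129	Android LMI	ROR2	9	94486321	T	C	0.67	0.019	0.002	3.34e-15	0.002	0.011	0.600
rs2242449	Total lean %	ACADVL/DLG4	17	7095507	T	C	0.43	-0.018	0.002	6.94e-15	-0.035	0.011	7.40e-03
rs4832298	Leg FMI	CHMP3	2	86764004	T	C	0.69	-0.019	0.002	1.10e-14	0.006	0.011	0.781
rs7893571	Android fat mass	RSU1	10	16750129	T	G	0.66	0.018	0.002	1.51e-14	-0.008	0.012	0.781
rs11525873	Android LMI	ZC3HAV1/TTC26	7	138817193	C	T	0.1	-0.029	0.004	2.88e-14	-0.011	0.018	0.493
rs6557791	Leg FMR	FAM160B2	8	21949663	C	T	0.6	-0.018	0.002	3.44e-14	0.001	0.011	0.691
rs12274114	Android LMI	LRP5/PPP6R3	11	68255577	C	A	0.28	-0.019	0.003	5.18e-14	-0.023	0.012	0.102
rs1441264	SFI	LINC00331	13	79580919	A	G	0.59	0.018	0.002	6.02e-14	-0.013	0.011	0.875
rs2504236	Android LMI	FLT3	13	28613298	T	C	0.59	-0.017	0.002	1.11e-13	-0.014	0.011	0.216
rs4660586	Gynoid fat mass	HIVEP3	1	42407229	T	C	0.74	-0.019	0.003	1.82e-13	0.005	0.012	0.781
rs59893724	SAT	SSBP2	5	80830788	G	A	0.25	-0.019	0.003	6.00e-13	-0.019	0.012	0.182
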