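transcript	n_snps	avg_reads	strand	snp_id	jxo_alt	jxo_ref	oxj_ref	oxj_alt	af_jxo	af_oxj	fdr	sequenom	igv	counts_reconstructed
AF357425	13	32	+	chr12_110872195	47	0	47	0	1.00	0.00	1.52E-23	.	MAT	no
AK050713	12	27	+	chr12_110907826	31	0	22	0	1.00	0.00	2.64E-11	.	MAT	no
Asb4	7	19	+	chr6_5348300	19	0	9	2	1.00	0.18	0.045042863	MAT	MAT	no
Cdkn1c	31	29	-	chr7_150644367	202	1	133	0	1.00	0.00	4.16E-91	MAT	MAT	no
Grb10	205	106	-	chr11_11831012	1789	7	1600	4	1.00	0.00	0	MAT	MAT	no
H19	67	323	-	chr7_149761651	7298	4	5969	8	1.00	0.00	0	MAT	MAT	no
Igf2r	14	136	-	chr17_12876894	167	3	244	5	0.98	0.02	1.22E-102	MAT	MAT	no
Meg3	20	133	+	chr12_110783337	139	0	1180	1	1.00	0.00	2.55E-72	MAT	MAT	no
Mirg	66	35	+	chr12_110980023	56	0	39	0	1.00	0.00	1.74E-23	.	MAT	no
Rian	20	298	+	chr12_110884294	926	10	712	0	0.99	0.00	0	MAT	MAT	no
Rtl1as	2	18	+	chr12_110831619	20	0	22	0	1.00	0.00	2.36E-08	MAT	MAT	no
Airn	1	13	+	chr17_13008045	0	13	0	12	0.00	1.00	0.001142434	PAT	PAT	no
Blcap	1	55	-	chr2_157387807	0	42	5	63	0.00	0.93	1.98E-23	.	PAT	yes
D7Ertd715e	5	14	-	chr7_67115005	0	13	0	17	0.00	1.00	5.01E-05	PAT	PAT	no
Igf2	61	706	-	chr7_149836880	1	8277	25	2589	0.00	0.99	0	PAT	PAT	yes
Igf2as	2	31	+	chr7_149853327	0	36	0	55	0.00	1.00	2.22E-22	PAT	PAT	no
Impact	14	187	+	chr18_13133281	6	187	12	180	0.03	0.94	3.05E-146	PAT	PAT	yes
Kcnq1ot1	201	22	-	chr7_150427528	0	14	0	22	0.00	1.00	1.60E-06	PAT	PAT	no
Mest	13	80	+	chr6_30695854	1	300	14	450	0.00	0.97	8.79E-200	.	PAT	yes
Ndn	1	67	+	chr7_69493343	0	59	0	74	0.00	1.00	1.97E-35	.	PAT	no
Nespas	2	11	-	chr2_174107316	0	12	0	9	0.00	1.00	0.020011567	PAT	PAT	no
Nnat	4	79	+	chr2_157387776	2	177	7	170	0.01	0.96	8.59E-28	PAT	PAT	yes
Peg10	10	115	+	chr6_4707869	0	115	0	94	0.00	1.00	4.06E-58	PAT	PAT	no
Peg12	3	39	-	chr7_69608449	0	44	0	47	0.00	1.00	3.23E-23	PAT	PAT	no
Peg13	5	31	-	chr15_72639823	0	15	0	52	0.00	1.00	1.80E-11	PAT	PAT	no
Peg3	17	53	-	chr7_6662661	0	49	1	42	0.00	0.98	9.36E-22	PAT	PAT	yes
Plagl1	18	45	+	chr10_12844715	0	46	0	47	0.00	1.00	7.81E-24	PAT	PAT	no
Sgce	4	81	-	chr6_4639630	0	103	0	108	0.00	1.00	3.78E-59	.	PAT	no
Slc38a4	19	350	-	chr15_96825404	21	189	13	1355	0.10	0.99	4.89E-86	PAT	PAT	yes
Snrpn	1	45	-	chr7_67133548	0	24	4	62	0.00	0.94	3.91E-18	PAT	PAT	yes
Snurf	1	45	-	chr7_67133548	0	24	4	62	0.00	0.94	3.91E-18	PAT	PAT	yes
Zdbf2	17	24	+	chr1_63360418	0	11	0	35	0.00	1.00	4.56E-07	PAT	PAT	no
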