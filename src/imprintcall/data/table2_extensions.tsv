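transcript	parent	novelty	strand	chrom	start	end	n_snps	avg_reads	snp_id	jxo_alt	jxo_ref	oxj_ref	oxj_alt	af_jxo	af_oxj	fdr	origin	sequenom	counts_reconstructed
Grb10_ext	Grb10	N	-	chr11	11824747	11830503	2	11	chr11_11828159	10	0	12	0	1.00	0.00	0.0182	MAT	.	no
Meg3_ext	Meg3	N	+	chr12	110809913	110828360	11	15	chr12_110826437	14	0	13	0	1.00	0.00	0.0006	MAT	MAT	no
Nespas_ext	Nespas	E	-	chr2	174091931	174106739	15	23	chr2_174092928	0	24	0	22	0.00	1.00	0.0000	PAT	.	no
Peg12_ext	Peg12	E	-	chr7	69603714	69606757	2	16	chr7_69604676	1	23	0	12	0.04	1.00	0.0005	PAT	.	yes
Peg3_ext	Peg3	N	-	chr7	6656607	6658671	7	68	chr7_6658505	0	52	0	69	0.00	1.00	0.0000	PAT	.	no
Rian_ext	Rian	E	+	chr12	110899856	110967973	209	24	chr12_110903354	63	0	52	0	1.00	0.00	0.0000	MAT	MAT	no
Rtl1as_ext	Rtl1as	N	+	chr12	110831619	110842153	15	17	chr12_110841979	25	1	31	0	0.96	0.00	0.0000	MAT	.	no
Snurf_ext	Snurf	N	-	chr7	67119318	67126070	6	12	chr7_67121406	0	11	0	12	0.00	1.00	0.0044	PAT	.	no
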