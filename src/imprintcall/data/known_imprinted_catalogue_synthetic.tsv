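gene	known_origin	category	subcategory	expressed	has_snp
AF357425	MATERNAL	ok	found_candidate	yes	yes
AK050713	MATERNAL	ok	found_candidate	yes	yes
Asb4	MATERNAL	ok	found_candidate	yes	yes
Cdkn1c	MATERNAL	ok	found_candidate	yes	yes
Grb10	MATERNAL	ok	found_candidate	yes	yes
H19	MATERNAL	ok	found_candidate	yes	yes
Igf2r	MATERNAL	ok	found_candidate	yes	yes
Meg3	MATERNAL	ok	found_candidate	yes	yes
Mirg	MATERNAL	ok	found_candidate	yes	yes
Rian	MATERNAL	ok	found_candidate	yes	yes
Rtl1as	MATERNAL	ok	found_candidate	yes	yes
Airn	PATERNAL	ok	found_candidate	yes	yes
Blcap	PATERNAL	ok	found_candidate	yes	yes
D7Ertd715e	PATERNAL	ok	found_candidate	yes	yes
Igf2	PATERNAL	ok	found_candidate	yes	yes
Igf2as	PATERNAL	ok	found_candidate	yes	yes
Impact	PATERNAL	ok	found_candidate	yes	yes
Kcnq1ot1	PATERNAL	ok	found_candidate	yes	yes
Mest	PATERNAL	ok	found_candidate	yes	yes
Ndn	PATERNAL	ok	found_candidate	yes	yes
Nespas	PATERNAL	ok	found_candidate	yes	yes
Nnat	PATERNAL	ok	found_candidate	yes	yes
Peg10	PATERNAL	ok	found_candidate	yes	yes
Peg12	PATERNAL	ok	found_candidate	yes	yes
Peg13	PATERNAL	ok	found_candidate	yes	yes
Peg3	PATERNAL	ok	found_candidate	yes	yes
Plagl1	PATERNAL	ok	found_candidate	yes	yes
Sgce	PATERNAL	ok	found_candidate	yes	yes
Slc38a4	PATERNAL	ok	found_candidate	yes	yes
Snrpn	PATERNAL	ok	found_candidate	yes	yes
Snurf	PATERNAL	ok	found_candidate	yes	yes
Zdbf2	PATERNAL	ok	found_candidate	yes	yes
unk_lowexpr_01	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_02	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_03	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_04	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_05	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_06	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_07	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_08	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_09	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_10	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_11	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_12	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_13	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_14	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_15	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_16	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_17	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_18	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_19	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_20	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_21	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_22	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_23	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_24	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_25	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_26	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_27	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_28	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_29	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_30	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_31	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_32	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_33	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_34	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_35	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_36	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_37	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_38	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_39	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_40	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_41	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_42	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_43	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_44	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_45	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_46	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_47	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_48	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_49	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_50	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_51	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_52	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_53	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_54	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_55	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_56	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_57	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_58	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_59	PATERNAL	ok	low_expression	no	yes
unk_lowexpr_60	MATERNAL	ok	low_expression	no	yes
unk_lowexpr_61	PATERNAL	ok	low_expression	no	yes
unk_nosnp_1	PATERNAL	ok	no_snp	yes	no
unk_nosnp_2	MATERNAL	ok	no_snp	yes	no
unk_nosnp_3	PATERNAL	ok	no_snp	yes	no
unk_nosnp_4	MATERNAL	ok	no_snp	yes	no
unk_nosnp_5	PATERNAL	ok	no_snp	yes	no
Dlk1	PATERNAL	ok	leaky	yes	yes
unk_tissue_01	PATERNAL	ok	tissue_specific	yes	yes
unk_tissue_02	MATERNAL	ok	tissue_specific	yes	yes
unk_tissue_03	PATERNAL	ok	tissue_specific	yes	yes
unk_tissue_04	MATERNAL	ok	tissue_specific	yes	yes
unk_tissue_05	PATERNAL	ok	tissue_specific	yes	yes
unk_tissue_06	MATERNAL	ok	tissue_specific	yes	yes
unk_tissue_07	PATERNAL	ok	tissue_specific	yes	yes
unk_tissue_08	MATERNAL	ok	tissue_specific	yes	yes
unk_tissue_09	PATERNAL	ok	tissue_specific	yes	yes
unk_tissue_10	MATERNAL	ok	tissue_specific	yes	yes
unk_tissue_11	PATERNAL	ok	tissue_specific	yes	yes
unk_tissue_12	MATERNAL	ok	tissue_specific	yes	yes
unk_tissue_13	PATERNAL	ok	tissue_specific	yes	yes
unk_tissue_14	MATERNAL	ok	tissue_specific	yes	yes
unk_limited_1	PATERNAL	ok	limited_info	yes	yes
unk_limited_2	MATERNAL	ok	limited_info	yes	yes
unk_limited_3	PATERNAL	ok	limited_info	yes	yes
unk_limited_4	MATERNAL	ok	limited_info	yes	yes
unk_smallrna_01	PATERNAL	small_rna	.	.	.
unk_smallrna_02	MATERNAL	small_rna	.	.	.
unk_smallrna_03	PATERNAL	small_rna	.	.	.
unk_smallrna_04	MATERNAL	small_rna	.	.	.
unk_smallrna_05	PATERNAL	small_rna	.	.	.
unk_smallrna_06	MATERNAL	small_rna	.	.	.
unk_smallrna_07	PATERNAL	small_rna	.	.	.
unk_smallrna_08	MATERNAL	small_rna	.	.	.
unk_smallrna_09	PATERNAL	small_rna	.	.	.
unk_smallrna_10	MATERNAL	small_rna	.	.	.
unk_smallrna_11	PATERNAL	small_rna	.	.	.
unk_smallrna_12	MATERNAL	small_rna	.	.	.
unk_smallrna_13	PATERNAL	small_rna	.	.	.
unk_smallrna_14	MATERNAL	small_rna	.	.	.
unk_smallrna_15	PATERNAL	small_rna	.	.	.
unk_smallrna_16	MATERNAL	small_rna	.	.	.
unk_smallrna_17	PATERNAL	small_rna	.	.	.
unk_smallrna_18	MATERNAL	small_rna	.	.	.
unk_smallrna_19	PATERNAL	small_rna	.	.	.
unk_smallrna_20	MATERNAL	small_rna	.	.	.
unk_smallrna_21	PATERNAL	small_rna	.	.	.
unk_smallrna_22	MATERNAL	small_rna	.	.	.
unk_notgenuine_01	PATERNAL	not_genuine	.	.	.
unk_notgenuine_02	MATERNAL	not_genuine	.	.	.
unk_notgenuine_03	PATERNAL	not_genuine	.	.	.
unk_notgenuine_04	MATERNAL	not_genuine	.	.	.
unk_notgenuine_05	PATERNAL	not_genuine	.	.	.
unk_notgenuine_06	MATERNAL	not_genuine	.	.	.
unk_notgenuine_07	PATERNAL	not_genuine	.	.	.
unk_notgenuine_08	MATERNAL	not_genuine	.	.	.
unk_notgenuine_09	PATERNAL	not_genuine	.	.	.
unk_notgenuine_10	MATERNAL	not_genuine	.	.	.
unk_notgenuine_11	PATERNAL	not_genuine	.	.	.
unk_notgenuine_12	MATERNAL	not_genuine	.	.	.
A19	MATERNAL	duplicate	.	.	.
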