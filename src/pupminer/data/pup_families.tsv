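# Packaged PUP family catalog: 26 families, 6 enzyme classes, 60 seeds.
# The per-seed substrate table is not published; substrate labels here are
# synthetic per-family placeholders (substrate_<family>) so that substrate
# inference is exercised without inventing real chemical assignments.
family_id	enzyme_class	signature_domains	n_seeds	substrates	swissprot	trembl	uhgp
FR1	FR	Alpha-amylase	3	substrate_fr1	184	2537	4385
FR2	FR	Glyco_hydro_70	2	substrate_fr2	6	758	1534
FR3	FR	Arylsulfotrans+Arylsulfotran_N	1	substrate_fr3	1	226	2183
FR4	FR	PTase_Orf2	1	substrate_fr4	5	70	0
OR1	OR	ADH_zinc_N+ADH_N_2	1	substrate_or1	706	4350	1991
OR2	OR	Rieske+Ring_hydroxyl_A	1	substrate_or2	40	2456	64
OR3	OR	Oxidored_FMN+Pyr_redox_2	6	substrate_or3	8	3588	2729
OR4	OR	FAD_binding_2	4	substrate_or4	189	1585	2521
OR5	OR	adh_short_C2	4	substrate_or5	944	1233	80
OR6	OR	HpaB+HpaB_N	1	substrate_or6	12	3373	3335
OR7	OR	FMN_red	2	substrate_or7	2	1185	4859
OR8	OR	Cupin_2	2	substrate_or8	252	3671	1526
OR9	OR	NAD_binding_10	2	substrate_or9	223	702	768
HR1	HR	Glyco_hydro_1	3	substrate_hr1	197	1326	1386
HR2	HR	Glyco_hydro_11	1	substrate_hr2	86	3701	306
HR3	HR	Glyco_hydro_3+Fn3-like+Glyco_hydro_3_C	5	substrate_hr3	105	4825	3979
HR4	HR	AP_endonuc_2	3	substrate_hr4	518	1235	2245
HR5	HR	GFO_IDH_MocA	3	substrate_hr5	191	1190	4785
HR6	HR	Glyco_hydro_106	2	substrate_hr6	1	999	4462
HR7	HR	Bac_rhamnosid6H	6	substrate_hr7	0	3715	3950
HR8	HR	DAPG_hydrolase	2	substrate_hr8	1	348	155
IR1	IR	Glyoxalase_4	1	substrate_ir1	35	12	27
IR2	IR	Chalcone_N	1	substrate_ir2	0	78	30
NCR1	NCR	Amidohydro_2	1	substrate_ncr1	20	3048	953
UC1	UC		1	substrate_uc1	0	1275	346
UC2	UC		1	substrate_uc2	2062	3420	2558
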