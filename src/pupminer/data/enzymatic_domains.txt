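# Pfam domains treated as enzymatic when deriving family signatures.
# One domain name per line; lines starting with '#' are ignored.
Alpha-amylase
Glyco_hydro_70
Arylsulfotrans
Arylsulfotran_N
PTase_Orf2
ADH_zinc_N
ADH_N_2
Rieske
Ring_hydroxyl_A
Oxidored_FMN
Pyr_redox_2
FAD_binding_2
adh_short_C2
HpaB
HpaB_N
FMN_red
Cupin_2
NAD_binding_10
Glyco_hydro_1
Glyco_hydro_11
Glyco_hydro_3
Fn3-like
Glyco_hydro_3_C
AP_endonuc_2
GFO_IDH_MocA
Glyco_hydro_106
Bac_rhamnosid6H
DAPG_hydrolase
Glyoxalase_4
Chalcone_N
Amidohydro_2
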