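variable,kind,sle_pos_mean,sle_pos_sd,sle_pos_count,sle_pos_n,sle_neg_mean,sle_neg_sd,sle_neg_count,sle_neg_n
age_years,numeric,13.7,11.6,,7,16.2,9.6,,32
sex_male,categorical,,,3,7,,,21,32
AST,numeric,378,317.3,,7,172,235.5,,32
ALT,numeric,277,220.6,,7,216,327.1,,32
PT,numeric,95.4,13.1,,7,95.9,24.0,,32
aPTT,numeric,33.3,4.6,,7,31.5,6.0,,32
F_IX,numeric,49.5,14.9,,7,75.2,25.0,,32
F_XI,numeric,35.9,15.1,,7,59.3,35.5,,32
AT_III,numeric,43.0,14.1,,7,51.2,26.8,,32
Protein_C,numeric,38.6,17.2,,7,83.4,129.9,,32
Protein_S,numeric,52.9,22.6,,7,63.5,17.5,,32
mvrd,numeric,0.48,0.10,,7,0.41,0.10,,32
vascular_personal,categorical,,,1,7,,,3,32
vascular_familial,categorical,,,1,7,,,2,32
febrile_seizures,categorical,,,2,7,,,4,32
epilepsy,categorical,,,2,7,,,6,32
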