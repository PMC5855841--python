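episode_id,patient_id,sex,age_text,trigger,free_interval_h,focal_deficit,irritability,decreased_consciousness,seizures,temperature_c,eeg_abnormal,mri_finding,cns_infection_at_onset,alternative_diagnosis,treatment,duration_h,icars,synthetic
1,1,M,3 yr 11 mo,head_trauma,3,1,0,1,1,38.5,1,hemispheric_edema,0,0,LEV;PHE;MDZ,96,,0
2,2,M,15 yr,head_trauma,24,0,0,1,0,37.4,0,none,0,0,,48,,0
3,3,F,5 yr,head_trauma,4,0,0,1,0,37.5,0,none,0,0,,7,46,0
4-I,4,F,3 yr 6 mo,head_trauma,1,0,1,1,0,38.0,0,none,0,0,,3,8,0
4-II,4,F,14 yr 5 mo,infection,,1,1,0,0,38.0,0,none,0,0,LEV,36,,0
5-I,5,F,7 yr 4 mo,head_trauma,12,1,1,1,0,38.6,0,none,0,0,risperidone,168,56,0
5-II,5,F,10 yr 2 mo,head_trauma,2,0,1,1,0,38.5,0,none,0,0,MDZ,24,,0
6,6,F,3 yr 3 mo,infection,,0,1,1,1,38.9,1,none,0,0,LEV;PHE;MDZ,264,,0
7,7,M,5 yr 8 mo,infection,,1,0,1,1,38.5,1,none,0,0,VPA;LEV;DZP;MDZ,144,65,0
X1,X1,M,6 yr,unknown,,1,0,0,0,37.8,0,ischemic_stroke,0,0,,,,1
X2,X2,F,4 yr,infection,,0,0,1,1,38.8,1,none,1,0,,,,1
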