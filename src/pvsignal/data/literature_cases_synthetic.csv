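drug,sex,source_kind,age_years,region,preexisting_ibd,family_history_ibd,indication,smoking,prior_tnf,onset_months,ibd_class,symptoms,wbc,crp,esr,fecal_calprotectin,ct_findings,colonoscopy_findings,histopathology_findings,therapy,outcome,relief_weeks
secukinumab,female,case_report,19.0,USA,true,true,PsO,yes,adalimumab,0.47,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,elevated,elevated,elevated,elevated,bowel_wall_thickening,deep_ulcerations;edematous,chronic_inflammation;granulomatous_lesions,none,recovered,1.0
secukinumab,female,case_report,27.0,USA,true,true,PsO,yes,adalimumab,0.5,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,elevated,elevated,elevated,elevated,bowel_wall_thickening,deep_ulcerations;edematous,chronic_inflammation;granulomatous_lesions,corticosteroids,recovered,1.5
secukinumab,female,case_report,28.0,USA,true,true,PsO,yes,adalimumab,0.6,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,elevated,elevated,elevated,elevated,bowel_wall_thickening,deep_ulcerations;edematous,chronic_inflammation;granulomatous_lesions,corticosteroids,recovered,1.8
secukinumab,female,case_report,30.0,USA,false,true,PsO,yes,adalimumab,0.7,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,elevated,elevated,elevated,elevated,bowel_wall_thickening,deep_ulcerations;edematous,chronic_inflammation;granulomatous_lesions,corticosteroids,recovered,2.0
secukinumab,female,case_report,31.0,USA,false,true,PsO,yes,adalimumab,0.9,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,elevated,elevated,elevated,,bowel_wall_thickening,deep_ulcerations;edematous,chronic_inflammation;granulomatous_lesions,corticosteroids,recovered,2.3
secukinumab,female,case_report,33.0,USA,false,false,PsO,yes,adalimumab,1.2,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,elevated,elevated,elevated,,pancolitis,deep_ulcerations;friable_mucosa,chronic_inflammation;granulomatous_lesions,corticosteroids,recovered,2.6
secukinumab,female,case_report,34.0,USA,false,false,PsO,yes,adalimumab,1.5,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,elevated,elevated,normal,,pancolitis,deep_ulcerations;friable_mucosa,chronic_inflammation;granulomatous_lesions,corticosteroids,recovered,3.0
secukinumab,female,case_report,35.0,USA,false,false,PsO,yes,adalimumab,1.8,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,normal,elevated,,,colon_perforated,deep_ulcerations;friable_mucosa,chronic_inflammation,corticosteroids,recovered,3.3
secukinumab,female,case_report,36.0,USA,false,false,PsO,no,adalimumab,2.0,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,,elevated,,,normal,deep_ulcerations;friable_mucosa,chronic_inflammation,corticosteroids,recovered,3.6
secukinumab,female,case_report,38.0,USA,false,false,PsO,no,adalimumab,2.2,UC,abdominal_pain;bloody_diarrhea;diarrhea;fever,,elevated,,,normal,absent_vascular_pattern;deep_ulcerations,chronic_inflammation,corticosteroids,recovered,3.9
secukinumab,female,case_report,39.0,USA,false,false,PsO,no,adalimumab,2.5,UC,abdominal_pain;bloody_diarrhea;diarrhea;weight_loss,,elevated,,,,absent_vascular_pattern;deep_ulcerations,chronic_inflammation,corticosteroids,recovered,5.0
secukinumab,female,case_report,40.0,Europe,false,false,PsO,no,adalimumab,2.6,UC,abdominal_pain;bloody_diarrhea;diarrhea;weight_loss,,elevated,,,,absent_vascular_pattern;deep_ulcerations,cryptitis,tnf_antagonist,recovered,6.0
secukinumab,female,case_report,41.0,Europe,false,false,PsO,not_mentioned,adalimumab,2.7,UC,abdominal_pain;bloody_diarrhea;diarrhea;weight_loss,,elevated,,,,absent_vascular_pattern;deep_ulcerations,cryptitis,tnf_antagonist,recovered,8.0
secukinumab,female,case_report,42.0,Europe,false,false,PsO,not_mentioned,etanercept,2.9,CD,abdominal_pain;bloody_diarrhea;diarrhea;weight_loss,,elevated,,,,active_inflammation;hemorrhagic,cryptitis,tnf_antagonist,recovered,10.0
secukinumab,female,case_report,42.0,Europe,false,false,PsO,not_mentioned,etanercept,3.0,CD,abdominal_pain;bloody_diarrhea;diarrhea;weight_loss,,elevated,,,,active_inflammation;hemorrhagic,cryptitis,tnf_antagonist,recovered,12.0
secukinumab,female,case_report,42.0,Europe,false,false,PsO,not_mentioned,etanercept,3.5,CD,abdominal_pain;bloody_diarrhea;chills;diarrhea,,elevated,,,,active_inflammation;hemorrhagic,cryptitis,tnf_antagonist,recovered,
secukinumab,female,case_report,42.0,Europe,false,false,PsO,not_mentioned,etanercept,4.0,CD,abdominal_pain;bloody_diarrhea;chills;diarrhea,,,,,,active_inflammation,cryptitis,tnf_antagonist,recovered,
secukinumab,male,case_report,42.0,Europe,false,false,PsO,not_mentioned,etanercept,4.5,CD,abdominal_pain;chills;diarrhea,,,,,,active_inflammation,crypt_abscesses;cryptitis,ustekinumab,recovered,
secukinumab,male,case_report,43.0,Europe,false,false,PsO,not_mentioned,etanercept,5.0,CD,abdominal_pain;chills;diarrhea,,,,,,active_inflammation,crypt_abscesses;cryptitis,ustekinumab,recovered,
secukinumab,male,case_report,45.0,Europe,false,false,PsO,not_mentioned,etanercept,5.5,CD,diarrhea;nausea,,,,,,active_inflammation,crypt_abscesses,five_asa,recovered,
secukinumab,male,case_report,46.0,Europe,false,false,PsA,not_mentioned,etanercept,5.9,CD,diarrhea;nausea,,,,,,active_inflammation,crypt_abscesses,corticosteroids_plus_tnf_antagonist,recovered,
secukinumab,male,case_report,48.0,Europe,false,false,PsA,not_mentioned,etanercept,6.5,CD,diarrhea;nausea,,,,,,superficial_ulceration,crypt_abscesses,corticosteroids_plus_tnf_antagonist,recovered,
secukinumab,male,case_report,49.0,Europe,false,false,PsA,not_mentioned,etanercept,8.0,CD,diarrhea;nausea,,,,,,erythematous_mucosa;superficial_ulceration,crypt_abscesses,corticosteroids_plus_tnf_antagonist,recovered,
secukinumab,male,case_report,50.0,Europe,false,false,PsA,not_mentioned,etanercept,11.0,unclassified,diarrhea,,,,,,erythematous_mucosa;superficial_ulceration,crypt_abscesses,corticosteroids_plus_tnf_antagonist,recovered,
secukinumab,male,case_report,51.0,Canada,false,false,PsO_and_PsA,not_mentioned,,13.0,unclassified,diarrhea,,,,,,erythematous_mucosa;superficial_ulceration,crypt_abscesses,corticosteroids_plus_tnf_antagonist,recovered,
secukinumab,male,case_series,53.0,Canada,false,false,PsO_and_PsA,not_mentioned,,20.0,unclassified,diarrhea,,,,,,erythematous_mucosa;superficial_ulceration,,corticosteroids_plus_tnf_antagonist,recovered,
secukinumab,male,case_series,55.0,Canada,false,false,PsO_and_PsA,not_mentioned,,48.0,unclassified,diarrhea,,,,,,erythematous_mucosa;superficial_ulceration,,corticosteroids_plus_five_asa,recovered,
ixekizumab,male,case_series,58.0,Canada,false,false,AS,not_mentioned,,,unclassified,diarrhea,,,,,,erythematous_mucosa,,corticosteroids_plus_five_asa,relapse,
ixekizumab,male,case_series,60.0,Canada,false,false,AS,not_mentioned,,,,fever,,,,,,,,corticosteroids_plus_five_asa,relapse,
ixekizumab,male,,63.0,Canada,false,false,AS,not_mentioned,,,,fever,,,,,,,,corticosteroids_plus_five_asa,,
ixekizumab,male,,66.0,Asia,false,false,AS,not_mentioned,,,,diarrhea,,,,,,,,corticosteroids_plus_ustekinumab,,
ixekizumab,male,,70.0,Asia,false,false,AS,not_mentioned,,,,diarrhea,,,,,,,,,,
ixekizumab,male,,74.0,other,false,false,AS,not_mentioned,,,,asymptomatic,,,,,,,,,,
ixekizumab,male,,76.0,,false,false,AS,not_mentioned,,,,,,,,,,,,,,
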