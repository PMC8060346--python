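# Observed and model-predicted pharmacokinetic parameters for captopril,
# transcribed at printed precision from the published evaluation tables:
# source_table 4 (iv bolus, healthy), 6 (oral, healthy), 7 (oral, chronic
# kidney disease and chronic heart failure). Units: AUC0_inf ng/mL.h,
# CL L/h (apparent oral clearance CL/F for oral routes), Cmax ng/mL.
# scenario_id joins to study_designs.csv.
# printed_ratio is the ratio column as printed; note one row (severe CKD CL) prints 0.69 while its own observed/predicted
# quotient rounds to 0.68 -- the transcription preserves the print.
scenario_id,source_table,population,route,food_state,label,dose_mg,parameter,observed,predicted,printed_ratio
iv_2.78mg,4,healthy,iv_bolus,fasted,2.78 mg,2.78,AUC0_inf,67.48,66.81,1.01
iv_5.67mg,4,healthy,iv_bolus,fasted,5.67 mg,5.67,AUC0_inf,123.21,134.70,0.91
iv_10mg,4,healthy,iv_bolus,fasted,10 mg,10,AUC0_inf,178.99,218.48,0.82
iv_11.4mg,4,healthy,iv_bolus,fasted,11.4 mg,11.4,AUC0_inf,310.82,279.21,1.11
iv_2.78mg,4,healthy,iv_bolus,fasted,2.78 mg,2.78,CL,41.20,41.61,0.99
iv_5.67mg,4,healthy,iv_bolus,fasted,5.67 mg,5.67,CL,46.01,42.09,1.09
iv_10mg,4,healthy,iv_bolus,fasted,10 mg,10,CL,55.86,45.77,1.22
iv_11.4mg,4,healthy,iv_bolus,fasted,11.4 mg,11.4,CL,36.67,40.83,0.90
iv_2.78mg,4,healthy,iv_bolus,fasted,2.78 mg,2.78,Cmax,105.61,101.34,1.04
iv_5.67mg,4,healthy,iv_bolus,fasted,5.67 mg,5.67,Cmax,120.52,206.91,0.58
iv_10mg,4,healthy,iv_bolus,fasted,10 mg,10,Cmax,461.41,446.00,1.03
iv_11.4mg,4,healthy,iv_bolus,fasted,11.4 mg,11.4,Cmax,458.73,471.04,0.97
oral_10mg,6,healthy,oral,fasted,10 mg,10,AUC0_inf,100.51,115.68,0.87
oral_25mg,6,healthy,oral,fasted,25 mg,25,AUC0_inf,335.59,304.54,1.10
oral_25mg_test,6,healthy,oral,fasted,25 mg (Test),25,AUC0_inf,348.67,318.55,1.09
oral_25mg_reference,6,healthy,oral,fasted,25 mg (Reference),25,AUC0_inf,334.03,317.78,1.05
oral_50mg,6,healthy,oral,fasted,50 mg,50,AUC0_inf,625.14,603.02,1.04
oral_100mg_fasted,6,healthy,oral,fasted,100 mg (Fasted),100,AUC0_inf,1339.39,1233.91,1.09
oral_100mg_fed,6,healthy,oral,fed,100 mg (Fed),100,AUC0_inf,782.07,1232.38,0.63
oral_100mg_male,6,healthy,oral,fasted,100 mg (Male),100,AUC0_inf,789.28,1121.55,0.70
oral_100mg_female,6,healthy,oral,fasted,100 mg (Female),100,AUC0_inf,781.54,1094.16,0.71
oral_100mg,6,healthy,oral,fasted,100 mg,100,AUC0_inf,1198.67,1191.55,1.01
oral_100mg_geriatric,6,geriatric,oral,fasted,100 mg (Geriatrics),100,AUC0_inf,1415.87,1223.04,1.16
oral_10mg,6,healthy,oral,fasted,10 mg,10,CL,99.48,86.45,1.15
oral_25mg,6,healthy,oral,fasted,25 mg,25,CL,74.49,82.09,0.91
oral_25mg_test,6,healthy,oral,fasted,25 mg (Test),25,CL,71.70,78.48,0.91
oral_25mg_reference,6,healthy,oral,fasted,25 mg (Reference),25,CL,74.84,78.67,0.95
oral_50mg,6,healthy,oral,fasted,50 mg,50,CL,79.98,82.92,0.96
oral_100mg_fasted,6,healthy,oral,fasted,100 mg (Fasted),100,CL,74.66,81.04,0.92
oral_100mg_fed,6,healthy,oral,fed,100 mg (Fed),100,CL,127.86,81.14,1.58
oral_100mg_male,6,healthy,oral,fasted,100 mg (Male),100,CL,126.69,89.16,1.42
oral_100mg_female,6,healthy,oral,fasted,100 mg (Female),100,CL,127.95,91.39,1.40
oral_100mg,6,healthy,oral,fasted,100 mg,100,CL,83.42,83.92,0.99
oral_100mg_geriatric,6,geriatric,oral,fasted,100 mg (Geriatrics),100,CL,70.62,81.76,0.86
oral_10mg,6,healthy,oral,fasted,10 mg,10,Cmax,66.48,72.96,0.91
oral_25mg,6,healthy,oral,fasted,25 mg,25,Cmax,138.09,192.29,0.72
oral_25mg_test,6,healthy,oral,fasted,25 mg (Test),25,Cmax,215.01,192.29,1.12
oral_25mg_reference,6,healthy,oral,fasted,25 mg (Reference),25,Cmax,218.99,192.29,1.14
oral_50mg,6,healthy,oral,fasted,50 mg,50,Cmax,231.26,384.61,0.60
oral_100mg_fasted,6,healthy,oral,fasted,100 mg (Fasted),100,Cmax,848.14,739.91,1.15
oral_100mg_fed,6,healthy,oral,fed,100 mg (Fed),100,Cmax,338.75,792.63,0.43
oral_100mg_male,6,healthy,oral,fasted,100 mg (Male),100,Cmax,480.65,750.21,0.64
oral_100mg_female,6,healthy,oral,fasted,100 mg (Female),100,Cmax,466.16,817.07,0.57
oral_100mg,6,healthy,oral,fasted,100 mg,100,Cmax,768.17,747.28,1.03
oral_100mg_geriatric,6,geriatric,oral,fasted,100 mg (Geriatrics),100,Cmax,735.90,676.34,1.09
ckd_mild_100mg,7,ckd_mild,oral,fasted,100 mg (Mild),100,AUC0_inf,1886.24,1715.13,1.10
ckd_moderate_100mg,7,ckd_moderate,oral,fasted,100 mg (Moderate),100,AUC0_inf,2469.66,2321.50,1.06
ckd_severe_100mg,7,ckd_severe,oral,fasted,100 mg (Severe),100,AUC0_inf,6733.48,4612.70,1.46
chf_25mg,7,chf,oral,fasted,25 mg,25,AUC0_inf,375.72,507.41,0.74
ckd_mild_100mg,7,ckd_mild,oral,fasted,100 mg (Mild),100,CL,53.01,58.30,0.91
ckd_moderate_100mg,7,ckd_moderate,oral,fasted,100 mg (Moderate),100,CL,40.49,43.08,0.94
ckd_severe_100mg,7,ckd_severe,oral,fasted,100 mg (Severe),100,CL,14.85,21.68,0.69
chf_25mg,7,chf,oral,fasted,25 mg,25,CL,66.54,49.27,1.35
ckd_mild_100mg,7,ckd_mild,oral,fasted,100 mg (Mild),100,Cmax,650,654.72,0.99
ckd_moderate_100mg,7,ckd_moderate,oral,fasted,100 mg (Moderate),100,Cmax,644,618.76,1.04
ckd_severe_100mg,7,ckd_severe,oral,fasted,100 mg (Severe),100,Cmax,981,877.54,1.12
chf_25mg,7,chf,oral,fasted,25 mg,25,Cmax,240.21,240.56,1.00
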