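# Clinical study designs used for model development and evaluation:
# 9 healthy-adult studies contributing 15 concentration profiles
# (4 iv bolus + 11 oral) and 2 disease studies contributing 3 CKD and 1 CHF
# profiles; one row per profile/scenario (19 rows).
# Where the source table leaves a weight range blank, the healthy-adult
# default 60-85 kg is substituted; a blank female fraction is recorded as 0.
# The 25 mg healthy crossover study (n=24) lists female fraction 0.167 with
# age 19-25 y and weight 45-86 kg; the ambiguous column alignment in the
# source was resolved against the cited reference study design.
# food_state: fasted/fed; fed scenarios are simulated as fasted (the model
# carries no food-effect mechanism) and retained for evaluation.
scenario_id,study,population,n_subjects,dose_mg,route,fraction_female,age_min,age_max,weight_min,weight_max,food_state,label,source_table
iv_2.78mg,2,healthy,7,2.78,iv_bolus,0.0,20,33,60,85,fasted,2.78 mg,4
iv_5.67mg,2,healthy,7,5.67,iv_bolus,0.0,20,33,60,85,fasted,5.67 mg,4
iv_10mg,1,healthy,5,10,iv_bolus,0.0,24,34,68.1,88.7,fasted,10 mg,4
iv_11.4mg,2,healthy,7,11.4,iv_bolus,0.0,20,33,60,85,fasted,11.4 mg,4
oral_10mg,4,healthy,5,10,oral,0.0,24,34,68.1,88.7,fasted,10 mg,6
oral_25mg,5,healthy,12,25,oral,0.0,20,24,60,85,fasted,25 mg,6
oral_25mg_test,3,healthy,24,25,oral,0.167,19,25,45,86,fasted,25 mg (Test),6
oral_25mg_reference,3,healthy,24,25,oral,0.167,19,25,45,86,fasted,25 mg (Reference),6
oral_50mg,5,healthy,12,50,oral,0.0,20,24,60,85,fasted,50 mg,6
oral_100mg_fasted,8,healthy,12,100,oral,0.0,18,33,60,106,fasted,100 mg (Fasted),6
oral_100mg_fed,8,healthy,12,100,oral,0.0,18,33,60,106,fed,100 mg (Fed),6
oral_100mg_male,6,healthy,12,100,oral,0.0,21.88,25.78,67.53,76.85,fasted,100 mg (Male),6
oral_100mg_female,6,healthy,12,100,oral,1.0,19.55,25.61,51.47,60,fasted,100 mg (Female),6
oral_100mg,7,healthy,10,100,oral,0.0,18,35,64.2,85,fasted,100 mg,6
oral_100mg_geriatric,9,geriatric,12,100,oral,0.0,65,76,63,89,fasted,100 mg (Geriatrics),6
ckd_mild_100mg,10,ckd_mild,4,100,oral,0.75,19,60,57,109.5,fasted,100 mg (Mild),7
ckd_moderate_100mg,10,ckd_moderate,6,100,oral,0.33,21,55,54.3,95.6,fasted,100 mg (Moderate),7
ckd_severe_100mg,10,ckd_severe,8,100,oral,0.62,19,62,47.4,90,fasted,100 mg (Severe),7
chf_25mg,11,chf,20,25,oral,0.0,47,71,60,85,fasted,25 mg,7
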