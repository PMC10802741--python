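variable,level,drug,group,category,count,n_patients,n_samples,printed_pct
female_sex,patient,MMF,responder,yes,28,34,103,82.3
female_sex,patient,MMF,non-responder,yes,9,10,27,90.0
female_sex,patient,AZA,responder,yes,9,11,24,81.8
female_sex,patient,AZA,non-responder,yes,9,9,30,100.0
female_sex,patient,HC,responder,yes,53,56,133,94.6
female_sex,patient,HC,non-responder,yes,12,14,40,85.7
female_sex,patient,SOC,responder,yes,70,73,173,95.9
female_sex,patient,SOC,non-responder,yes,21,25,64,80.0
race,patient,MMF,responder,C,22,34,103,64.7
race,patient,MMF,responder,AA,7,34,103,20.59
race,patient,MMF,responder,O,5,34,103,14.7
race,patient,MMF,non-responder,C,2,10,27,20.0
race,patient,MMF,non-responder,AA,7,10,27,70.0
race,patient,MMF,non-responder,O,1,10,27,10.0
race,patient,AZA,responder,C,6,11,24,54.5
race,patient,AZA,responder,AA,4,11,24,36.4
race,patient,AZA,responder,O,1,11,24,9.1
race,patient,AZA,non-responder,C,3,9,30,33.3
race,patient,AZA,non-responder,AA,5,9,30,55.6
race,patient,AZA,non-responder,O,1,9,30,11.1
race,patient,HC,responder,C,19,56,133,33.9
race,patient,HC,responder,AA,34,56,133,60.7
race,patient,HC,responder,O,3,56,133,5.4
race,patient,HC,non-responder,C,4,14,40,28.6
race,patient,HC,non-responder,AA,9,14,40,64.3
race,patient,HC,non-responder,O,1,14,40,7.1
race,patient,SOC,responder,C,26,73,173,35.6
race,patient,SOC,responder,AA,44,73,173,60.3
race,patient,SOC,responder,O,3,73,173,4.1
race,patient,SOC,non-responder,C,8,25,64,32.0
race,patient,SOC,non-responder,AA,15,25,64,60.0
race,patient,SOC,non-responder,O,2,25,64,8.0
family_history,patient,MMF,responder,yes,11,34,103,32.25
family_history,patient,MMF,non-responder,yes,4,10,27,40.0
family_history,patient,AZA,responder,yes,2,11,24,18.18
family_history,patient,AZA,non-responder,yes,2,9,30,22.22
family_history,patient,HC,responder,yes,18,56,133,32.14
family_history,patient,HC,non-responder,yes,6,14,40,42.85
family_history,patient,SOC,responder,yes,26,73,173,35.62
family_history,patient,SOC,non-responder,yes,10,25,64,40.0
plaquenil,sample,MMF,responder,yes,79,34,103,76.7
plaquenil,sample,MMF,non-responder,yes,20,10,27,74.1
plaquenil,sample,AZA,responder,yes,20,11,24,83.3
plaquenil,sample,AZA,non-responder,yes,25,9,30,83.3
plaquenil,sample,HC,responder,yes,130,56,133,97.7
plaquenil,sample,HC,non-responder,yes,40,14,40,100.0
plaquenil,sample,SOC,responder,yes,170,73,173,98.3
plaquenil,sample,SOC,non-responder,yes,63,25,64,98.4
nsaid,sample,MMF,responder,yes,5,34,103,4.9
nsaid,sample,MMF,non-responder,yes,3,10,27,11.1
nsaid,sample,AZA,responder,yes,2,11,24,8.3
nsaid,sample,AZA,non-responder,yes,2,9,30,6.7
nsaid,sample,HC,responder,yes,46,56,133,34.6
nsaid,sample,HC,non-responder,yes,3,14,40,7.5
nsaid,sample,SOC,responder,yes,56,73,173,32.4
nsaid,sample,SOC,non-responder,yes,10,25,64,15.6
antihypertensive,sample,MMF,responder,yes,72,34,103,69.9
antihypertensive,sample,MMF,non-responder,yes,21,10,27,77.8
antihypertensive,sample,AZA,responder,yes,16,11,24,66.7
antihypertensive,sample,AZA,non-responder,yes,20,9,30,66.7
antihypertensive,sample,HC,responder,yes,78,56,133,58.6
antihypertensive,sample,HC,non-responder,yes,22,14,40,55.0
antihypertensive,sample,SOC,responder,yes,99,73,173,57.2
antihypertensive,sample,SOC,non-responder,yes,41,25,64,64.1
diuretic,sample,MMF,responder,yes,28,34,103,27.2
diuretic,sample,MMF,non-responder,yes,9,10,27,33.3
diuretic,sample,AZA,responder,yes,7,11,24,29.2
diuretic,sample,AZA,non-responder,yes,7,9,30,23.3
diuretic,sample,HC,responder,yes,41,56,133,30.8
diuretic,sample,HC,non-responder,yes,13,14,40,32.5
diuretic,sample,SOC,responder,yes,58,73,173,33.5
diuretic,sample,SOC,non-responder,yes,21,25,64,32.8
calcium_channel,sample,MMF,responder,yes,13,34,103,12.6
calcium_channel,sample,MMF,non-responder,yes,2,10,27,7.4
calcium_channel,sample,AZA,responder,yes,7,11,24,29.2
calcium_channel,sample,AZA,non-responder,yes,7,9,30,23.3
calcium_channel,sample,HC,responder,yes,18,56,133,13.5
calcium_channel,sample,HC,non-responder,yes,4,14,40,10.0
calcium_channel,sample,SOC,responder,yes,20,73,173,11.6
calcium_channel,sample,SOC,non-responder,yes,11,25,64,17.2
ace_inhibitor,sample,MMF,responder,yes,66,34,103,64.1
ace_inhibitor,sample,MMF,non-responder,yes,20,10,27,74.1
ace_inhibitor,sample,AZA,responder,yes,14,11,24,58.3
ace_inhibitor,sample,AZA,non-responder,yes,18,9,30,60.0
ace_inhibitor,sample,HC,responder,yes,60,56,133,45.1
ace_inhibitor,sample,HC,non-responder,yes,15,14,40,37.5
ace_inhibitor,sample,SOC,responder,yes,73,73,173,42.2
ace_inhibitor,sample,SOC,non-responder,yes,32,25,64,50.0
statin,sample,MMF,responder,yes,37,34,103,35.9
statin,sample,MMF,non-responder,yes,6,10,27,22.2
statin,sample,AZA,responder,yes,5,11,24,20.8
statin,sample,AZA,non-responder,yes,8,9,30,26.7
statin,sample,HC,responder,yes,23,56,133,17.3
statin,sample,HC,non-responder,yes,3,14,40,7.5
statin,sample,SOC,responder,yes,29,73,173,16.8
statin,sample,SOC,non-responder,yes,12,25,64,18.8
anti_dsdna,patient,MMF,responder,yes,28,34,103,82.4
anti_dsdna,patient,MMF,non-responder,yes,8,10,27,80.0
anti_dsdna,patient,AZA,responder,yes,7,11,24,63.6
anti_dsdna,patient,AZA,non-responder,yes,8,9,30,88.9
anti_dsdna,patient,HC,responder,yes,22,56,133,39.3
anti_dsdna,patient,HC,non-responder,yes,11,14,40,78.6
anti_dsdna,patient,SOC,responder,yes,31,73,173,42.5
anti_dsdna,patient,SOC,non-responder,yes,18,25,64,72.0
anti_sm,patient,MMF,responder,yes,15,34,103,44.1
anti_sm,patient,MMF,non-responder,yes,3,10,27,30.0
anti_sm,patient,AZA,responder,yes,2,11,24,18.2
anti_sm,patient,AZA,non-responder,yes,2,9,30,22.2
anti_sm,patient,HC,responder,yes,3,56,133,5.4
anti_sm,patient,HC,non-responder,yes,3,14,40,21.4
anti_sm,patient,SOC,responder,yes,4,73,173,5.5
anti_sm,patient,SOC,non-responder,yes,8,25,64,32.0
anti_ana,patient,MMF,responder,yes,32,34,103,94.1
anti_ana,patient,MMF,non-responder,yes,10,10,27,100.0
anti_ana,patient,AZA,responder,yes,10,11,24,90.9
anti_ana,patient,AZA,non-responder,yes,9,9,30,100.0
anti_ana,patient,HC,responder,yes,73,56,133,100.0
anti_ana,patient,HC,non-responder,yes,25,14,40,100.0
anti_ana,patient,SOC,responder,yes,73,73,173,100.0
anti_ana,patient,SOC,non-responder,yes,25,25,64,100.0
anti_ro,patient,MMF,responder,yes,13,34,103,38.2
anti_ro,patient,MMF,non-responder,yes,4,10,27,40.0
anti_ro,patient,AZA,responder,yes,5,11,24,45.5
anti_ro,patient,AZA,non-responder,yes,3,9,30,33.3
anti_ro,patient,HC,responder,yes,17,56,133,30.4
anti_ro,patient,HC,non-responder,yes,5,14,40,35.7
anti_ro,patient,SOC,responder,yes,21,73,173,28.8
anti_ro,patient,SOC,non-responder,yes,9,25,64,36.0
anti_la,patient,MMF,responder,yes,7,34,103,20.6
anti_la,patient,MMF,non-responder,yes,2,10,27,20.0
anti_la,patient,AZA,responder,yes,1,11,24,9.1
anti_la,patient,AZA,non-responder,yes,2,9,30,22.2
anti_la,patient,HC,responder,yes,9,56,133,16.1
anti_la,patient,HC,non-responder,yes,2,14,40,14.3
anti_la,patient,SOC,responder,yes,10,73,173,13.7
anti_la,patient,SOC,non-responder,yes,3,25,64,12.0
anti_rnp,patient,MMF,responder,yes,16,34,103,47.1
anti_rnp,patient,MMF,non-responder,yes,5,10,27,50.0
anti_rnp,patient,AZA,responder,yes,1,11,24,9.1
anti_rnp,patient,AZA,non-responder,yes,4,9,30,44.4
anti_rnp,patient,HC,responder,yes,9,56,133,16.1
anti_rnp,patient,HC,non-responder,yes,3,14,40,21.4
anti_rnp,patient,SOC,responder,yes,11,73,173,15.1
anti_rnp,patient,SOC,non-responder,yes,8,25,64,32.0
anti_b2gly,patient,MMF,responder,yes,12,34,103,35.3
anti_b2gly,patient,MMF,non-responder,yes,3,10,27,30.0
anti_b2gly,patient,AZA,responder,yes,2,11,24,18.2
anti_b2gly,patient,AZA,non-responder,yes,4,9,30,44.4
anti_b2gly,patient,HC,responder,yes,13,56,133,23.2
anti_b2gly,patient,HC,non-responder,yes,5,14,40,35.7
anti_b2gly,patient,SOC,responder,yes,17,73,173,23.3
anti_b2gly,patient,SOC,non-responder,yes,9,25,64,36.0
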