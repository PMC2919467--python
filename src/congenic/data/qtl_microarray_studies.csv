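study_id,species,design,n_candidates,n_platform_probes,n_selected_gw,n_selected_qtl,phenotype,platform
rat_hypertension_dsdr_cong,rat,Congenic,198,26379,45,3,Hypertension,RGU34
rat_hypertension_dslew_cong,rat,Congenic,267,26379,27,0,Hypertension,RGU34
rat_hypertension_shrsp_cong,rat,Congenic,78,26379,20,1,Hypertension,RGU34
rat_kidney_stones_cong,rat,Congenic,551,31042,50,16,Kidney stones,RAE230
rat_aerobic_capacity_par,rat,Parental,467,26379,199,9,Aerobic running capacity,RGU34
mouse_anxiety_cong,mouse,Congenic,187,45037,9,3,Anxiety,MOE430
mouse_ibd_cong,mouse,Congenic,5541,12488,94,16,IBD,U74Av2
mouse_macronutrient_cong,mouse,Congenic,1230,32991,3101,185,Macronutrient intake,ABI
mouse_obesity_fl_cong,mouse,Congenic,503,14938,13,1,Obesity,Spotted
mouse_osteoporosis_cong,mouse,Congenic,27,8734,283,1,Osteoporosis,Spotted
mouse_t1d_cong,mouse,Congenic,1294,39000,170,17,Type I diabetes,Affy.Eos.Custom
mouse_alcohol_haft_par,mouse,Parental,3251,12488,169,6,Alcohol addiction,MGU74Av2
mouse_alcohol_b6d2_par,mouse,Parental,4423,12488,996,151,Alcohol addiction,U74Av2
mouse_arthritis_par,mouse,Parental,649,22000,1396,18,Arthritis,MOE430A
mouse_gallstones_par,mouse,Parental,416,8734,57,0,Gallstones,Spotted
mouse_hscp_par,mouse,Parental,867,5184,200,11,HSCP,Filter
mouse_obesity_du6i_par,mouse,Parental,5079,13069,77,14,Obesity,Mu11k
mouse_pulmonary_par,mouse,Parental,1261,31775,933,1,Pulmonary capacity,Spotted/Operon
mouse_eiad_ext,mouse,Extremes,460,15000,30,0,EIAD,NIA15k
mouse_obesity_spret_ext,mouse,Extremes,1610,11000,50,5,Obesity,Spotted
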