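species,c_pct,c_pct_se,n_pct,n_pct_se,cn_ratio,cn_ratio_se,moisture_pct_fw,moisture_pct_fw_se,ph,ph_se,bulk_density_g_cm3,bulk_density_g_cm3_se,horizon_depth_cm,horizon_depth_cm_se
E. hermaphroditum,49.1,0.3,1.23,0.01,40,0,76.0,1.0,5.1,0.1,0.105,0.010,8.1,0.3
A. alpinus,48.6,0.6,1.31,0.10,38,3,75.4,1.0,5.3,0.3,0.107,0.007,9.5,0.8
B. nana,45.7,1.8,1.29,0.03,36,2,74.6,1.0,5.7,0.2,0.092,0.009,10.3,0.7
H. splendens,44.3,1.8,1.46,0.06,31,1,76.0,1.0,6.4,0.2,0.084,0.008,10.2,0.5
A. turgidum,43.5,1.4,1.51,0.08,29,2,79.0,0.5,6.9,0.2,0.061,0.007,9.3,0.4
T. nitens,40.8,3.2,1.38,0.09,30,3,77.6,1.6,7.0,0.0,0.066,0.012,9.8,0.6
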