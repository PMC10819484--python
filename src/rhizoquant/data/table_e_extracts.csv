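sample,water_content_pct,dry_matter_pct,total_n_pct,organic_matter_pct,organic_c_pct,n_nh4_mg_kg,n_no3_mg_kg,ph,conductivity_ms_cm,protein_pct,fibre_pct,carbohydrates_pct,lipids_pct,ash_pct,ca_mg_kg,k_mg_kg,mg_mg_kg,na_mg_kg,p_mg_kg,cd_mg_kg,ni_mg_kg,pb_mg_kg,zn_mg_kg,as_mg_kg
GNT,98.57,1.43,0.0018,99.02,57.44,581.0,0.39,6.74,8.88,0.011,0.07,0.43,0.37,0.01,218.3,2460.5,216.8,144.1,670.7,0.034,1.723,0.164,3.585,0.217
GT,98.40,1.60,0.0016,99.35,57.63,563.7,0.39,6.73,9.14,0.010,0.11,0.50,0.39,0.01,121.9,2243.2,138.3,147.6,586.1,0.059,0.695,0.224,5.901,0.253
WNT,98.43,1.57,0.0029,99.65,57.80,820.3,0.32,5.19,9.76,0.018,0.03,2.48,0.13,0.01,44.8,1253.0,96.4,224.5,361.0,0.055,0.235,0.081,4.023,0.214
WT,98.43,1.57,0.0027,99.64,57.79,696.7,0.22,5.31,9.22,0.017,0.06,2.39,0.10,0.01,12.3,1152.8,81.4,207.6,314.5,0.041,0.168,0.051,2.420,0.335
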