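sample,water_content_pct,dry_matter_pct,total_n_pct,organic_matter_pct,organic_c_pct,n_nh4_mg_kg,n_no3_mg_kg,ph,conductivity_ms_cm,protein_pct,fibre_pct,carbohydrates_pct,lipids_pct,ash_pct,ca_mg_kg,k_mg_kg,mg_mg_kg,na_mg_kg,p_mg_kg,cd_mg_kg,ni_mg_kg,pb_mg_kg,zn_mg_kg,as_mg_kg
GNT,19.53,80.47,1.97,88.10,51.10,4741.0,3.82,7.20,4.63,11.15,14.25,2.27,1.46,9.58,4412.0,19276.0,7152.2,974.1,9592.5,0.136,49.533,0.901,93.167,0.228
GT,36.00,64.00,1.28,88.83,51.52,4770.1,3.02,7.04,4.56,7.73,11.94,2.68,1.16,7.15,2064.7,19378.0,6833.3,987.8,9670.3,0.120,42.033,0.714,89.267,0.243
WNT,13.40,86.60,1.86,93.53,54.25,5980.3,2.47,7.32,5.09,11.60,,23.43,1.61,5.60,1317.4,11698.1,3765.5,2022.3,5288.0,0.124,27.200,1.671,55.167,0.133
WT,15.10,84.90,1.60,93.72,54.36,6270.0,2.49,7.64,4.60,10.13,,22.82,1.56,5.33,1044.7,11333.0,3679.8,1944.4,5039.4,0.535,25.200,0.819,50.600,0.128
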