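sample,water_content_pct,dry_matter_pct,total_n_pct,organic_matter_pct,organic_c_pct,n_nh4_mg_kg,n_no3_mg_kg,ph,conductivity_ms_cm,protein_pct,fibre_pct,carbohydrates_pct,lipids_pct,ash_pct,ca_mg_kg,k_mg_kg,mg_mg_kg,na_mg_kg,p_mg_kg,cd_mg_kg,ni_mg_kg,pb_mg_kg,zn_mg_kg,as_mg_kg
GNT,97.00,3.00,0.0061,98.98,57.41,1597.7,0.76,6.32,12.22,0.038,0.25,0.42,0.24,0.03,425.6,3362.3,631.2,261.3,1124.9,0.044,3.533,0.155,7.400,0.060
GT,97.10,2.90,0.0039,99.07,57.46,1228.3,0.60,6.26,11.63,0.024,0.13,0.51,0.21,0.02,446.6,3284.4,627.3,262.9,1096.3,0.042,3.167,0.186,7.100,0.057
WNT,97.50,2.50,0.0088,99.34,57.62,2287.7,0.46,6.28,13.78,0.055,,4.38,0.34,0.02,42.8,2112.8,115.6,381.7,559.9,0.037,0.800,0.320,5.200,0.059
WT,97.40,2.60,0.0062,99.40,57.66,1865.3,0.46,6.74,13.11,0.039,,4.26,0.32,0.02,44.6,2085.6,112.3,378.4,556.2,0.034,0.600,0.296,5.067,0.056
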