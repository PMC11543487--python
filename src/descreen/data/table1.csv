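system_id,hba,hbd,ratio_hba,ratio_hbd,diluent,diluent_mass_fraction,ph,viscosity_mpa_s,density_g_per_cm3,co2_saturation_mg_per_l,k_nadh_star_per_min,ph_after_co2,residual_activity_14d_pct
ChCl:Gly_10%W,choline chloride,glycerol,1,2,water,0.10,7.51,77.88,1.17,282,0.004,6.95,0.0
ChCl:Gly_30%W,choline chloride,glycerol,1,2,water,0.30,6.60,18.98,1.14,480,0.000,6.03,47.6
ChCl:Gly_50%W,choline chloride,glycerol,1,2,water,0.50,7.12,4.16,1.09,702,0.009,5.68,42.1
ChCl:Gly_80%W,choline chloride,glycerol,1,2,water,0.80,6.48,2.27,1.03,825,0.009,4.89,52.0
ChCl:Gly_90%W,choline chloride,glycerol,1,2,water,0.90,6.25,1.48,1.02,965,0.000,4.8,0.0
ChCl:Gly_10%B,choline chloride,glycerol,1,2,buffer,0.10,9.19,82.63,1.17,465,0.000,6.88,0.0
ChCl:Gly_30%B,choline chloride,glycerol,1,2,buffer,0.30,8.75,19.61,1.14,727,0.000,6.89,95.1
ChCl:Gly_50%B,choline chloride,glycerol,1,2,buffer,0.50,8.33,5.74,1.11,913,0.003,6.79,11.8
ChCl:Gly_80%B,choline chloride,glycerol,1,2,buffer,0.80,7.75,2.50,1.06,1057,0.000,6.53,70.7
ChCl:Gly_90%B,choline chloride,glycerol,1,2,buffer,0.90,7.67,1.31,1.04,1149,0.000,6.49,40.3
B:Gly_10%W,betaine,glycerol,1,2,water,0.10,6.48,353.70,1.21,311,0.000,4.73,33.3
B:Gly_30%W,betaine,glycerol,1,2,water,0.30,5.96,20.86,1.15,618,0.001,4.26,70.0
B:Gly_50%W,betaine,glycerol,1,2,water,0.50,5.33,8.84,1.13,829,0.006,3.87,51.5
B:Gly_80%W,betaine,glycerol,1,2,water,0.80,5.29,2.27,1.04,1101,0.008,3.75,11.9
B:Gly_90%W,betaine,glycerol,1,2,water,0.90,5.47,1.31,1.03,1112,0.005,3.77,0.0
B:Gly_10%B,betaine,glycerol,1,2,buffer,0.10,7.85,219.05,1.21,509,0.003,6.39,60.0
B:Gly_30%B,betaine,glycerol,1,2,buffer,0.30,7.46,32.87,1.17,586,0.000,6.26,59.8
B:Gly_50%B,betaine,glycerol,1,2,buffer,0.50,7.45,6.45,1.13,765,0.001,6.24,65.0
B:Gly_80%B,betaine,glycerol,1,2,buffer,0.80,7.49,2.27,1.06,1027,0.009,6.24,58.5
B:Gly_90%B,betaine,glycerol,1,2,buffer,0.90,7.47,1.19,1.04,1010,0.000,6.31,48.3
buffer,none,none,0,0,buffer,1.00,7.50,1.39,1.02,1029,0.003,6.49,0.0
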