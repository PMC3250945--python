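sex,age_band,n_subgroup,p_cath_death_pct,anatomy,prevalence_pct,prevalence_n,p_revasc_pct,p_cabg_pct,n_utility,u_revasc_mean,u_revasc_sd,u_medical_mean,u_medical_sd
male,lt65,4684,0.01,left_main,5.3,247,84.2,92.8,275,0.77,0.26,0.81,0.21
male,lt65,4684,0.01,three_vessel,21.3,996,82.0,44.9,1094,0.80,0.22,0.80,0.21
male,lt65,4684,0.01,one_two_vessel,73.5,3441,53.6,13.5,3056,0.81,0.23,0.81,0.23
male,65_75,1992,0.03,left_main,11.0,220,81.8,90.6,273,0.80,0.22,0.77,0.26
male,65_75,1992,0.03,three_vessel,30.8,614,73.5,52.3,822,0.81,0.21,0.79,0.24
male,65_75,1992,0.03,one_two_vessel,58.1,1158,54.6,21.4,1070,0.82,0.23,0.81,0.23
male,gt75,1209,0.01,left_main,17.0,205,68.3,84.3,116,0.78,0.25,0.86,0.15
male,gt75,1209,0.01,three_vessel,36.2,438,67.1,42.5,350,0.82,0.21,0.81,0.22
male,gt75,1209,0.01,one_two_vessel,46.8,566,53.2,28.2,357,0.83,0.24,0.80,0.22
female,lt65,1722,0.01,left_main,2.3,40,92.5,83.8,45,0.76,0.25,0.87,0.14
female,lt65,1722,0.01,three_vessel,9.4,161,75.8,50.8,185,0.82,0.17,0.80,0.22
female,lt65,1722,0.01,one_two_vessel,88.3,1521,31.6,19.8,1181,0.81,0.21,0.82,0.22
female,65_75,1038,0.01,left_main,4.0,41,73.2,90.0,57,0.75,0.29,0.81,0.21
female,65_75,1038,0.01,three_vessel,18.1,188,68.1,39.8,209,0.80,0.22,0.81,0.24
female,65_75,1038,0.01,one_two_vessel,77.9,809,41.4,21.2,667,0.84,0.20,0.80,0.24
female,gt75,882,0.06,left_main,7.5,66,71.2,83.0,35,0.87,0.14,0.70,0.28
female,gt75,882,0.06,three_vessel,26.9,237,63.3,28.7,181,0.80,0.22,0.84,0.22
female,gt75,882,0.06,one_two_vessel,65.7,579,46.8,21.0,339,0.85,0.20,0.81,0.21
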