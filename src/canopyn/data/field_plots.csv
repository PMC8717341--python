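elevation_band,plot,elevation_m,dominant_species,mean_n_pct_dm,mean_dign_pct_dm,glider_count,predicted_mean_n_pct_dm,mean_likelihood,favorable_fraction_pct,clumpiness
lowlands,1,120,E. sieberi,1.01,0.95,0,1.16,0.61,30.28,0.78
lowlands,2,181,E. consideniana,1.37,0.81,0,1.32,0.63,46.01,0.67
lowlands,3,397,E. sieberi,1.00,,0,1.06,0.50,33.97,0.56
lowlands,4,222,E. polyanthemos,1.00,,0,1.19,0.47,7.25,0.64
lowlands,5,126,E. globoidea,0.94,0.88,0,1.00,0.42,14.21,0.68
lowlands,6,61,E. globoidea,1.01,0.87,0,1.17,0.55,23.73,0.73
lowlands,7,159,E. consideniana,1.12,0.84,0,1.15,0.56,29.13,0.73
lowlands,8,203,E. consideniana,0.88,0.81,0,0.99,0.36,13.43,0.46
lowlands,9,282,E. consideniana,0.89,0.84,0,1.11,0.38,14.86,0.48
lowlands,10,32,E. globoidea,1.20,0.90,2,1.23,0.61,29.65,0.74
mid_hills,1,439,E. obliqua,1.14,0.93,0,1.26,0.66,61.40,0.65
mid_hills,2,661,E. fastigata,1.14,0.97,1,1.24,0.88,88.09,0.85
mid_hills,3,777,E. cypellocarpa,1.39,0.92,1,1.30,0.64,25.11,0.78
mid_hills,4,679,E. sieberi,1.29,0.91,0,1.32,0.63,59.72,0.64
mid_hills,5,501,E. muelleriana,1.20,1.10,0,1.27,0.70,73.71,0.52
mid_hills,6,448,E. globulus subsp. pseudoglobulus,1.23,1.15,0,1.22,0.73,60.43,0.78
mid_hills,7,692,E. cypellocarpa,1.49,0.98,0,1.41,0.75,70.78,0.74
mid_hills,8,710,E. sieberi,1.16,1.16,0,1.31,0.86,87.74,0.75
mid_hills,9,720,E. fastigata,1.71,1.13,0,1.56,0.76,79.57,0.60
mid_hills,10,446,E. obliqua,1.44,,0,1.39,0.82,84.22,0.80
high,1,926,E. croajingolensis,1.60,,2,1.44,0.67,61.61,0.56
high,2,1001,E. croajingolensis,1.48,,0,1.44,0.68,63.51,0.64
high,3,1185,E. delegatensis,1.58,,0,1.45,0.57,51.49,0.66
high,4,1050,E. nitens,1.47,,0,1.42,0.74,39.20,0.87
high,5,907,E. viminalis,1.15,,2,1.25,0.88,64.77,0.94
high,6,937,E. croajingolensis,1.59,0.88,14,1.41,0.76,64.42,0.76
high,7,1072,E. cypellocarpa,1.75,1.12,3,1.52,0.71,65.53,0.68
high,8,920,E. obliqua,1.33,1.01,0,1.34,0.78,73.74,0.72
high,9,1117,E. obliqua,1.35,0.95,3,1.24,0.50,37.64,0.58
high,10,924,E. viminalis,1.67,1.20,5,1.54,0.64,57.33,0.60
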