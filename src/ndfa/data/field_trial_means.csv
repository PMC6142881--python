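site,landrace,shoot_dm_g,nodule_dm_mg,n_pct,n_content_mg,cn_ratio,delta15n,ndfa_pct,n_fixed_kg_ha,soil_n_kg_ha,grain_yield_kg_ha
Nyankpala,Puffeun,20.40,5.96,2.77,567.09,14.27,1.03,37.46,35.51,59.00,1484.00
Nyankpala,Dowie,22.58,7.01,2.92,653.42,14.79,,35.15,38.16,70.75,1136.65
Nyankpala,Funsi,27.04,7.36,2.86,773.93,14.29,1.07,37.02,46.30,82.68,1265.94
Nyankpala,Sigiri,26.36,5.97,2.94,777.20,14.47,1.65,29.57,38.18,91.35,1232.67
Nyankpala,Boli,22.76,8.92,3.04,689.16,14.71,,32.90,37.57,77.29,1556.21
Savelugu,Puffeun,16.52,4.85,2.89,504.02,11.69,1.59,21.04,17.10,66.90,1059.2
Savelugu,Dowie,16.22,6.28,3.03,491.81,11.83,1.64,20.36,15.86,66.11,931.5
Savelugu,Funsi,23.13,7.68,3.22,731.39,11.37,1.45,23.15,27.63,94.27,921.5
Savelugu,Sigiri,14.83,10.77,2.96,432.77,11.56,1.81,17.82,12.80,59.33,1040.0
Savelugu,Boli,17.01,2.85,3.14,516.40,11.53,1.82,17.79,15.16,70.91,1192.1
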