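genotype,pae_pminus_mean,pae_pminus_sd,prae_pminus_mean,prae_pminus_sd,pue_pminus_mean,pue_pminus_sd,pae_pplus_mean,pae_pplus_sd,prae_pplus_mean,prae_pplus_sd,pue_pplus_mean,pue_pplus_sd,relative_efficiency,apue
Advisor,57.86,3.48,0.00147,0.00018,37.54,2.53,36.79,9.72,0.02963,0.00205,181.86,75.69,15.2,40.96
Alessio,68.35,9.26,0.00157,0.00015,54.04,8.90,30.17,7.18,0.02879,0.00187,144.90,69.75,20.8,32.56
Annecy,55.23,7.75,0.00167,0.00019,32.85,16.69,28.45,2.73,0.03123,0.00064,77.40,20.85,20.0,26.83
Armada,62.15,5.55,0.00145,0.00015,57.34,17.38,27.88,6.35,0.02584,0.00262,158.15,38.17,19.7,34.59
Bagou,46.40,14.68,0.00148,0.00016,26.51,18.07,33.88,8.41,0.03278,0.00398,134.27,80.06,13.7,35.96
Calixo,56.25,11.28,0.00237,0.00008,29.48,4.26,30.44,1.34,0.03618,0.00162,144.64,23.07,15.6,35.78
CIMMYT4,70.29,14.19,0.00182,0.00012,51.40,15.59,29.03,4.25,0.03109,0.00198,122.03,42.69,17.9,30.59
CIMMYT10,88.39,9.91,0.00222,0.00016,45.80,11.32,26.60,2.33,0.03482,0.00441,77.23,16.83,21.9,23.19
CIMMYT11,56.10,11.28,0.00185,0.00017,28.56,10.31,30.64,1.93,0.03084,0.00121,100.09,29.40,27.2,30.01
CIMMYT12,73.46,14.45,0.00180,0.00023,40.16,14.60,20.17,8.46,0.0268,0.00294,66.03,48.33,18.6,19.00
CIMMYT15,62.71,10.61,0.00152,0.00013,49.68,3.92,33.65,7.82,0.02437,0.00387,175.23,69.46,13.8,37.93
Complice,76.70,19.24,0.00188,0.00020,50.53,23.30,33.43,4.39,0.03288,0.00342,148.26,18.02,19.5,35.68
Crusoe,53.62,7.47,0.00171,0.00014,32.21,13.28,36.39,5.69,0.03297,0.00243,179.03,68.00,13.6,41.54
Donator,41.50,5.15,0.00140,0.00020,30.87,4.15,32.16,4.86,0.03108,0.00311,104.44,32.79,16.8,31.92
Foxyl,59.09,3.99,0.00150,0.00006,37.24,7.91,35.74,4.18,0.02887,0.00066,154.74,45.10,15.4,38.87
Gedser,81.12,10.89,0.00170,0.00026,55.38,17.91,44.28,4.38,0.03072,0.00082,202.72,39.38,16.8,45.12
Hereward,58.35,13.05,0.00163,0.00004,37.28,9.28,36.36,3.05,0.02882,0.00064,187.82,36.89,14.6,42.08
Hyking,66.22,18.55,0.00169,0.00005,46.12,22.94,35.37,3.41,0.02966,0.00375,184.86,52.50,16.2,41.36
Ionesco,62.72,16.04,0.00176,0.00012,40.40,16.64,38.34,6.14,0.02929,0.00311,207.57,65.30,14.5,44.3
Johnson,53.39,11.07,0.00122,0.00017,43.99,14.38,28.41,2.81,0.02994,0.00253,113.54,14.49,19.8,29.74
Pibrac,68.81,11.52,0.00142,0.00006,53.12,10.50,34.62,5.63,0.03241,0.00439,138.48,36.04,20.4,34.68
RGT Lexio,61.81,12.60,0.00158,0.00010,48.89,17.98,35.34,7.50,0.03268,0.00575,176.10,47.01,16.5,42.27
RGT Libravo,59.25,2.29,0.00173,0.00016,35.43,9.44,44.06,3.59,0.03561,0.00147,146.12,89.66,17.0,35.17
Robigus,48.27,10.44,0.00165,0.00021,25.79,11.17,34.91,6.74,0.0282,0.00268,176.45,64.80,12.4,41.33
Rubisko,50.95,10.14,0.00143,0.00014,37.87,14.53,31.22,4.80,0.0292,0.00130,140.47,38.63,16.7,35.02
Soissons,68.06,13.82,0.00153,0.00003,67.33,27.78,41.01,3.94,0.02983,0.00097,263.52,73.75,16.1,48
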