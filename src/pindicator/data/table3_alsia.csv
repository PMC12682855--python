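genotype,pae_pminus_mean,pae_pminus_sd,prae_pminus_mean,prae_pminus_sd,pue_pminus_mean,pue_pminus_sd,pae_pplus_mean,pae_pplus_sd,prae_pplus_mean,prae_pplus_sd,pue_pplus_mean,pue_pplus_sd,relative_efficiency,apue
Advisor,20.75,2.45,0.004,0.00034,24.10,4.77,35.07,1.90,0.063,0.00421,165.28,32.71,47.69,59.8
Alessio,29.68,2.12,0.006,0.00035,89.95,18.01,62.53,3.29,0.059,0.00363,92.68,18.56,63.34,66.8
Annecy,20.87,0.69,0.006,0.00081,29.89,1.61,36.79,3.76,0.065,0.00840,157.53,8.49,66.15,51.6
Armada,22.39,2.26,0.006,0.00022,25.73,2.51,35.53,0.96,0.065,0.00223,163.14,15.94,73.93,35.7
Bagou,18.11,2.91,0.006,0.00178,38.49,3.76,51.64,12.24,0.075,0.02260,112.23,10.96,40.81,91.3
Calixo,19.77,0.98,0.011,0.00166,20.99,2.82,24.74,1.34,0.072,0.01098,234.25,31.51,79.73,44.5
CIMMYT4,24.88,2.91,0.010,0.00089,21.55,4.29,29.13,1.39,0.08097,0.00719,198.94,39.60,97.56,5.9
CIMMYT10,19.38,1.55,0.006,0.00076,24.45,3.07,22.93,1.98,0.083,0.01045,252.77,31.73,77.6,48.0
CIMMYT11,14.10,0.77,0.008,0.00119,27.36,3.31,19.79,1.35,0.100,0.01478,292.88,35.48,93.47,11.1
CIMMYT12,16.34,1.85,0.009,0.00078,28.42,4.16,22.21,1.65,0.111,0.00858,260.89,38.23,78.07,43.9
CIMMYT15,18.07,0.84,0.008,0.00061,27.42,3.58,36.15,1.82,0.080,0.00635,160.31,20.94,61.67,94.3
Complice,21.08,2.39,0.005,0.00121,21.83,2.71,29.78,4.48,0.066,0.01332,194.64,24.18,63.5,56.2
Crusoe,13.50,0.91,0.005,0.00031,18.03,3.43,22.88,0.98,0.071,0.00372,253.28,48.20,69.84,22.3
Donator,10.61,0.40,0.006,0.00038,16.25,2.79,20.22,0.93,0.078,0.00485,286.63,49.22,51.63,43.3
Foxyl,13.86,0.59,0.007,0.00107,29.79,4.51,25.09,3.02,0.073,0.01119,231.02,34.97,51.85,45.7
Gedser,21.85,1.45,0.006,0.00042,32.28,1.95,40.08,2.11,0.070,0.00506,144.60,8.73,41,97.2
Hereward,16.89,1.77,0.005,0.00047,19.37,5.54,22.89,1.71,0.006,0.00056,200.85,57.49,73.44,29.9
Hyking,50.34,2.98,0.006,0.00053,58.35,3.70,48.03,3.73,0.057,0.00530,120.67,7.65,94.19,8.8
Ionesco,31.15,2.96,0.005,0.00039,26.22,1.74,35.22,2.27,0.063,0.00491,164.55,10.94,44.93,66.8
Johnson,23.49,3.84,0.006,0.00043,22.10,3.33,26.70,1.65,0.052,0.00362,217.06,32.71,94.69,3.5
Pibrac,27.83,2.16,0.005,0.00062,25.23,5.58,38.51,3.14,0.070,0.00710,150.48,33.27,68.28,0.6
RGT Lexio,18.19,0.92,0.006,0.00029,23.35,1.10,30.50,1.39,0.061,0.00284,190.03,8.97,73.49,33.4
RGT Libravo,28.43,2.30,0.006,0.00034,83.57,4.40,59.49,2.40,0.058,0.00334,97.43,5.13,57.29,72.1
Robigus,13.82,1.69,0.007,0.00071,15.14,1.32,15.88,1.14,0.077,0.00762,364.95,31.90,88.41,9.4
Rubisko,14.28,1.11,0.007,0.00234,51.22,12.26,80.34,21.11,0.091,0.03029,72.14,17.27,36.95,98.0
Soissons,30.31,4.51,0.006,0.00072,27.59,1.59,34.25,3.27,0.061,0.00709,169.23,9.75,84.36,29.3
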