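population,group,N,C-M130,E-M96,F-M89,G-M201,H-M69,H1-M52,H1a-M197,H2-Apt,J-M304,J2-M172,J2a1-M47,J2a3-M68,K-M9,L1-M27,L3-M357,O-M175,P-M45,Q-M242,R-M207,R1a1-M17,R2-M124,nei_d,nei_sd
Paniya,HTF,72,15.28,0.00,75.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,1.39,1.39,0.00,0.00,0.00,1.39,1.39,2.78,1.39,0.418,0.067
Paliyan,HTF,95,10.53,0.00,55.79,2.11,2.11,11.58,0.00,0.00,0.00,9.47,0.00,0.00,0.00,2.11,3.16,0.00,0.00,0.00,0.00,3.16,0.00,0.659,0.049
Pulayar,HTF,63,1.59,0.00,57.14,0.00,6.35,11.11,0.00,0.00,0.00,15.87,0.00,0.00,0.00,1.59,1.59,0.00,1.59,3.17,0.00,0.00,0.00,0.640,0.060
Irula,HTF,80,6.25,0.00,36.25,0.00,18.75,7.50,0.00,8.75,0.00,1.25,0.00,0.00,0.00,16.25,0.00,0.00,0.00,1.25,1.25,0.00,2.50,0.799,0.028
Kadar,HTF,28,10.71,0.00,28.57,0.00,0.00,32.14,0.00,0.00,0.00,28.57,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.749,0.032
Kanikaran,HTC,17,0.00,0.00,11.76,5.88,0.00,29.41,0.00,0.00,0.00,5.88,0.00,0.00,0.00,23.53,0.00,0.00,0.00,5.88,5.88,5.88,5.88,0.875,0.058
Thoda,HTC,26,7.69,0.00,3.85,0.00,0.00,11.54,0.00,0.00,0.00,7.69,0.00,38.46,0.00,7.69,3.85,3.85,3.85,0.00,0.00,0.00,11.54,0.834,0.061
Kota,HTC,62,0.00,0.00,8.06,0.00,1.61,30.65,0.00,0.00,0.00,0.00,0.00,6.45,1.61,0.00,0.00,0.00,0.00,4.84,4.84,22.58,19.35,0.815,0.026
Betta Kurumba,HTK,17,0.00,0.00,58.82,0.00,0.00,11.76,0.00,0.00,0.00,0.00,0.00,0.00,0.00,17.65,0.00,0.00,0.00,0.00,0.00,5.88,5.88,0.640,0.116
Kattunaickan,HTK,46,2.17,0.00,21.74,0.00,17.39,41.30,0.00,0.00,2.17,4.35,0.00,0.00,0.00,0.00,0.00,0.00,0.00,2.17,4.35,0.00,4.35,0.761,0.044
Kurumba,HTK,35,2.86,0.00,11.43,0.00,2.86,65.71,0.00,0.00,0.00,0.00,0.00,0.00,2.86,5.71,0.00,0.00,0.00,0.00,0.00,2.86,5.71,0.561,0.096
Mullukurumba,HTK,29,0.00,0.00,20.69,0.00,0.00,34.48,0.00,0.00,0.00,0.00,0.00,0.00,3.45,24.14,0.00,0.00,0.00,0.00,0.00,0.00,17.24,0.776,0.036
Parayar NTN,SC,52,7.69,0.00,3.85,1.92,3.85,34.62,0.00,0.00,0.00,17.31,0.00,0.00,0.00,9.62,1.92,1.92,0.00,1.92,1.92,3.85,9.62,0.836,0.037
Parayar,SC,24,4.17,0.00,0.00,8.33,0.00,20.83,0.00,0.00,4.17,12.50,0.00,0.00,0.00,12.50,4.17,4.17,0.00,0.00,8.33,12.50,8.33,0.920,0.029
Pallar,SC,51,1.96,0.00,5.88,7.84,5.88,11.76,0.00,1.96,0.00,13.73,0.00,1.96,0.00,15.69,5.88,0.00,0.00,1.96,1.96,13.73,9.80,0.914,0.015
Paravar,SC,27,0.00,0.00,3.70,0.00,0.00,14.81,0.00,0.00,0.00,37.04,0.00,0.00,0.00,18.52,0.00,7.41,0.00,0.00,3.70,3.70,11.11,0.815,0.052
Yadhava,DLF,107,2.80,0.00,5.61,1.87,3.74,19.63,0.00,0.00,0.00,16.82,0.00,0.00,1.87,20.56,0.00,0.93,0.00,0.00,0.93,14.95,10.28,0.860,0.013
Vanniyar,DLF,21,0.00,0.00,9.52,4.76,0.00,4.76,0.00,0.00,0.00,14.29,0.00,9.52,0.00,28.57,0.00,0.00,0.00,0.00,0.00,14.29,14.29,0.876,0.043
Vanniyar NTN,DLF,96,7.29,1.04,8.33,3.13,3.13,13.54,0.00,3.13,0.00,7.29,0.00,2.08,0.00,23.96,2.08,2.08,0.00,0.00,2.08,11.46,9.38,0.889,0.016
Nadar TNV,DLF,59,0.00,0.00,8.47,8.47,11.86,15.25,0.00,1.69,0.00,5.08,0.00,0.00,0.00,28.81,0.00,0.00,0.00,3.39,0.00,6.78,10.17,0.861,0.025
Nadar Cape,DLF,98,4.08,4.08,5.10,9.18,7.14,7.14,0.00,1.02,0.00,9.18,0.00,1.02,0.00,23.47,0.00,1.02,1.02,9.18,1.02,12.24,4.08,0.895,0.015
Piramalai Kallar,DLF,53,9.43,0.00,5.66,3.77,3.77,16.98,0.00,1.89,0.00,1.89,0.00,0.00,1.89,47.17,1.89,0.00,0.00,0.00,0.00,1.89,3.77,0.745,0.055
Maravar,DLF,80,0.00,0.00,3.75,8.75,5.00,10.00,1.25,1.25,0.00,13.75,0.00,0.00,3.75,10.00,0.00,1.25,0.00,2.50,7.50,16.25,15.00,0.904,0.011
Valayar,AW,95,6.32,0.00,12.63,2.11,8.42,10.53,0.00,1.05,0.00,8.42,0.00,0.00,0.00,8.42,2.11,0.00,2.11,1.05,1.05,20.00,15.79,0.890,0.012
Tamil Jains,AW,100,4.00,0.00,2.00,2.00,3.00,22.00,0.00,3.00,0.00,11.00,0.00,0.00,1.00,9.00,2.00,2.00,0.00,1.00,0.00,18.00,20.00,0.862,0.015
Ezhava,AW,95,0.00,0.00,2.11,3.16,5.26,25.26,0.00,0.00,0.00,12.63,1.05,0.00,0.00,20.00,1.05,0.00,0.00,0.00,0.00,24.21,5.26,0.823,0.017
Mukkuvar,AW,17,0.00,0.00,0.00,0.00,0.00,17.65,0.00,11.76,0.00,17.65,0.00,0.00,0.00,5.88,0.00,0.00,0.00,0.00,11.76,11.76,23.53,0.890,0.040
Sourashtra,BRH,40,7.50,0.00,0.00,0.00,0.00,25.00,0.00,0.00,0.00,2.50,0.00,0.00,0.00,20.00,0.00,0.00,0.00,0.00,0.00,40.00,5.00,0.747,0.041
Brahacharanam,BRH,21,0.00,0.00,0.00,0.00,0.00,9.52,0.00,9.52,0.00,14.29,0.00,0.00,0.00,4.76,0.00,0.00,4.76,0.00,19.05,33.33,4.76,0.848,0.054
Iyengar,BRH,11,0.00,0.00,0.00,27.27,0.00,9.09,0.00,0.00,0.00,18.18,0.00,0.00,9.09,0.00,0.00,0.00,0.00,0.00,0.00,36.36,0.00,0.818,0.083
Vadama,BRH,63,3.17,0.00,1.59,4.76,0.00,7.94,0.00,3.17,0.00,4.76,0.00,0.00,1.59,14.29,1.59,3.17,0.00,0.00,6.35,47.62,0.00,0.746,0.052
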