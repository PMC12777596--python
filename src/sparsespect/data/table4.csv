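case_id,filter,mape_roi1,mape_roi2,nrmse,psnr,nb_roi1
1,none,28.15,16.71,0.1118,90.86,3.26
1,gaussian,27.78,16.62,0.1103,90.97,3.20
1,nlm,27.01,16.13,0.0974,92.10,3.12
2,none,22.56,35.16,0.2189,94.48,2.97
2,gaussian,21.94,24.83,0.2031,94.55,2.93
2,nlm,19.82,33.63,0.1887,94.80,2.88
3,none,6.70,32.14,0.1651,92.05,1.49
3,gaussian,6.14,31.85,0.1627,92.17,1.44
3,nlm,5.82,30.47,0.1467,93.07,1.36
4,none,38.74,7.11,0.0991,93.47,8.18
4,gaussian,36.66,6.90,0.0976,93.60,7.95
4,nlm,34.10,5.98,0.0867,94.63,7.63
5,none,23.11,25.38,0.1722,103.67,3.79
5,gaussian,22.02,24.97,0.1580,104.42,3.69
5,nlm,19.07,23.83,0.1229,106.60,3.53
6,none,10.09,18.90,0.2550,96.77,1.32
6,gaussian,7.43,18.52,0.2483,97.00,1.21
6,nlm,5.99,17.41,0.2229,97.94,1.10
7,none,6.97,51.90,0.1526,91.43,1.63
7,gaussian,6.36,50.43,0.1490,92.88,1.58
7,nlm,4.64,48.64,0.1371,94.16,1.55
8,none,11.42,8.30,0.0974,83.13,2.01
8,gaussian,11.04,6.24,0.0853,83.31,1.96
8,nlm,10.36,5.17,0.0930,84.53,1.80
9,none,41.91,28.05,0.2192,99.33,10.01
9,gaussian,39.22,27.45,0.2000,100.13,9.32
9,nlm,37.70,26.83,0.1553,102.33,9.09
10,none,10.94,44.17,0.1679,97.23,1.43
10,gaussian,10.19,43.66,0.1645,97.99,1.39
10,nlm,9.24,43.54,0.1598,98.41,1.27
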