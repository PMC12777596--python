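case_id,filter,mape_roi1,mape_roi2,nrmse,psnr,nb_roi1
1,none,15.27,5.64,0.0968,92.44,1.91
1,gaussian,14.79,5.20,0.0945,93.31,1.88
1,nlm,13.34,5.08,0.0778,94.00,1.83
2,none,13.48,4.97,0.1777,95.71,1.84
2,gaussian,12.81,4.12,0.1479,97.29,1.56
2,nlm,10.57,3.67,0.1078,100.04,1.50
3,none,1.81,4.22,0.1014,96.28,0.30
3,gaussian,1.68,4.01,0.0997,96.42,0.27
3,nlm,1.52,3.29,0.0909,97.22,0.23
4,none,3.32,5.07,0.0635,97.33,0.59
4,gaussian,3.06,4.99,0.0622,97.52,0.56
4,nlm,2.87,4.88,0.0566,98.34,0.46
5,none,3.78,12.32,0.1314,106.02,0.66
5,gaussian,2.38,10.90,0.1227,106.61,0.61
5,nlm,1.25,7.99,0.0969,108.67,0.54
6,none,5.94,18.10,0.1684,100.37,0.99
6,gaussian,3.69,17.79,0.1599,100.83,0.85
6,nlm,1.47,16.80,0.1323,102.47,0.81
7,none,2.15,30.23,0.1311,94.75,0.67
7,gaussian,0.89,28.43,0.1213,95.70,0.40
7,nlm,0.31,25.32,0.0946,96.68,0.35
8,none,9.56,0.84,0.0926,83.56,1.94
8,gaussian,8.88,0.70,0.0893,83.88,1.77
8,nlm,7.96,0.53,0.0787,84.98,1.58
9,none,13.64,2.15,0.1256,104.17,1.72
9,gaussian,11.72,1.79,0.1170,104.79,1.54
9,nlm,10.73,0.93,0.1030,105.89,1.39
10,none,0.66,12.22,0.1017,100.97,0.30
10,gaussian,0.64,3.24,0.0990,101.20,0.22
10,nlm,0.45,2.94,0.0925,101.79,0.09
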