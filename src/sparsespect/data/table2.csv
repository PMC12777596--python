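n_views,case_id,mape_roi1,mape_roi2,nrmse
30,1,15.27,5.64,0.0968
30,2,13.48,4.97,0.1777
30,3,1.81,4.22,0.1014
30,4,3.32,5.07,0.0635
30,5,3.78,12.32,0.1314
30,6,5.94,18.10,0.1684
30,7,2.15,30.23,0.1311
30,8,9.56,0.84,0.0926
30,9,13.64,2.15,0.1256
30,10,0.66,12.22,0.1017
15,1,28.15,16.71,0.1118
15,2,22.57,35.16,0.2189
15,3,6.70,32.14,0.1651
15,4,38.74,7.11,0.0991
15,5,23.11,25.38,0.1722
15,6,10.09,18.90,0.2550
15,7,6.97,51.90,0.1526
15,8,11.42,8.30,0.0974
15,9,41.91,28.05,0.2192
15,10,10.94,44.17,0.1679
10,1,85.48,60.69,0.4540
10,2,29.28,69.02,0.2872
10,3,32.31,90.78,0.3831
10,4,51.23,37.71,0.1861
10,5,61.44,40.51,0.2208
10,6,17.08,35.75,0.3099
10,7,53.59,59.87,0.2491
10,8,31.70,15.74,0.1470
10,9,58.26,52.80,0.2832
10,10,17.50,45.66,0.2471
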