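# Elemental photon mass attenuation coefficients mu/rho (cm^2/g), total
# attenuation with coherent scattering, on the standard NIST XCOM energy grid.
# Values transcribed from the NIST XCOM / Hubbell-Seltzer compilations to
# 3-4 significant figures. Log-log linear interpolation between nodes is
# intended; the biologically relevant elements have no absorption edges
# inside the 10 keV - 5 MeV range covered here.
element,energy_kev,mu_over_rho
H,10,0.3854
H,15,0.3764
H,20,0.3695
H,30,0.3570
H,40,0.3458
H,50,0.3355
H,60,0.3260
H,80,0.3091
H,100,0.2944
H,150,0.2651
H,200,0.2429
H,300,0.2112
H,400,0.1893
H,500,0.1729
H,600,0.1599
H,800,0.1405
H,1000,0.1263
H,1250,0.1129
H,1500,0.1027
H,2000,0.08769
H,3000,0.06921
H,4000,0.05806
H,5000,0.05049
C,10,2.373
C,15,0.8071
C,20,0.4420
C,30,0.2562
C,40,0.2076
C,50,0.1871
C,60,0.1753
C,80,0.1610
C,100,0.1514
C,150,0.1347
C,200,0.1229
C,300,0.1066
C,400,0.09546
C,500,0.08715
C,600,0.08058
C,800,0.07076
C,1000,0.06361
C,1250,0.05690
C,1500,0.05179
C,2000,0.04442
C,3000,0.03562
C,4000,0.03047
C,5000,0.02708
N,10,3.879
N,15,1.236
N,20,0.6178
N,30,0.3066
N,40,0.2288
N,50,0.1980
N,60,0.1817
N,80,0.1639
N,100,0.1529
N,150,0.1353
N,200,0.1233
N,300,0.1068
N,400,0.09557
N,500,0.08719
N,600,0.08063
N,800,0.07081
N,1000,0.06364
N,1250,0.05693
N,1500,0.05180
N,2000,0.04450
N,3000,0.03579
N,4000,0.03073
N,5000,0.02742
O,10,5.952
O,15,1.836
O,20,0.8651
O,30,0.3779
O,40,0.2585
O,50,0.2132
O,60,0.1907
O,80,0.1678
O,100,0.1551
O,150,0.1361
O,200,0.1237
O,300,0.1070
O,400,0.09566
O,500,0.08729
O,600,0.08070
O,800,0.07087
O,1000,0.06372
O,1250,0.05697
O,1500,0.05185
O,2000,0.04459
O,3000,0.03597
O,4000,0.03100
O,5000,0.02777
Na,10,15.42
Na,15,4.694
Na,20,2.100
Na,30,0.7300
Na,40,0.4105
Na,50,0.2977
Na,60,0.2485
Na,80,0.1926
Na,100,0.1698
Na,150,0.1417
Na,200,0.1275
Na,300,0.1100
Na,400,0.09836
Na,500,0.08970
Na,600,0.08288
Na,800,0.07272
Na,1000,0.06527
Na,1250,0.05834
Na,1500,0.05316
Na,2000,0.04575
Na,3000,0.03707
Na,4000,0.03224
Na,5000,0.02931
Mg,10,21.00
Mg,15,6.358
Mg,20,2.763
Mg,30,0.9306
Mg,40,0.5110
Mg,50,0.3565
Mg,60,0.2882
Mg,80,0.2148
Mg,100,0.1857
Mg,150,0.1521
Mg,200,0.1361
Mg,300,0.1168
Mg,400,0.1043
Mg,500,0.09504
Mg,600,0.08776
Mg,800,0.07698
Mg,1000,0.06908
Mg,1250,0.06175
Mg,1500,0.05628
Mg,2000,0.04848
Mg,3000,0.03940
Mg,4000,0.03439
Mg,5000,0.03138
P,10,40.30
P,15,12.88
P,20,5.500
P,30,1.700
P,40,0.8096
P,50,0.4916
P,60,0.3494
P,80,0.2324
P,100,0.1865
P,150,0.1432
P,200,0.1250
P,300,0.1055
P,400,0.09359
P,500,0.08511
P,600,0.07854
P,800,0.06884
P,1000,0.06182
P,1250,0.05526
P,1500,0.05026
P,2000,0.04324
P,3000,0.03541
P,4000,0.03090
P,5000,0.02797
S,10,50.12
S,15,16.02
S,20,6.708
S,30,2.113
S,40,0.9872
S,50,0.5849
S,60,0.4053
S,80,0.2586
S,100,0.2020
S,150,0.1506
S,200,0.1302
S,300,0.1091
S,400,0.09665
S,500,0.08781
S,600,0.08102
S,800,0.07098
S,1000,0.06373
S,1250,0.05697
S,1500,0.05193
S,2000,0.04467
S,3000,0.03667
S,4000,0.03206
S,5000,0.02905
Cl,10,57.00
Cl,15,18.40
Cl,20,7.870
Cl,30,2.426
Cl,40,1.117
Cl,50,0.6483
Cl,60,0.4395
Cl,80,0.2696
Cl,100,0.2050
Cl,150,0.1480
Cl,200,0.1266
Cl,300,0.1054
Cl,400,0.09311
Cl,500,0.08453
Cl,600,0.07795
Cl,800,0.06826
Cl,1000,0.06128
Cl,1250,0.05478
Cl,1500,0.04994
Cl,2000,0.04300
Cl,3000,0.03539
Cl,4000,0.03100
Cl,5000,0.02815
K,10,77.00
K,15,25.00
K,20,10.84
K,30,3.380
K,40,1.541
K,50,0.8679
K,60,0.5678
K,80,0.3251
K,100,0.2345
K,150,0.1582
K,200,0.1319
K,300,0.1080
K,400,0.09495
K,500,0.08600
K,600,0.07891
K,800,0.06909
K,1000,0.06199
K,1250,0.05542
K,1500,0.05048
K,2000,0.04365
K,3000,0.03610
K,4000,0.03178
K,5000,0.02899
Ca,10,95.00
Ca,15,30.50
Ca,20,13.06
Ca,30,4.080
Ca,40,1.830
Ca,50,1.019
Ca,60,0.6578
Ca,80,0.3656
Ca,100,0.2562
Ca,150,0.1669
Ca,200,0.1376
Ca,300,0.1119
Ca,400,0.09784
Ca,500,0.08851
Ca,600,0.08102
Ca,800,0.07104
Ca,1000,0.06366
Ca,1250,0.05699
Ca,1500,0.05212
Ca,2000,0.04526
Ca,3000,0.03780
Ca,4000,0.03398
Ca,5000,0.03159
Fe,10,170.6
Fe,15,57.08
Fe,20,25.68
Fe,30,8.176
Fe,40,3.629
Fe,50,1.958
Fe,60,1.205
Fe,80,0.5952
Fe,100,0.3717
Fe,150,0.1964
Fe,200,0.1460
Fe,300,0.1099
Fe,400,0.09400
Fe,500,0.08414
Fe,600,0.07704
Fe,800,0.06699
Fe,1000,0.05995
Fe,1250,0.05350
Fe,1500,0.04883
Fe,2000,0.04265
Fe,3000,0.03621
Fe,4000,0.03312
Fe,5000,0.03146
Cu,10,215.9
Cu,15,74.05
Cu,20,33.79
Cu,30,10.92
Cu,40,4.862
Cu,50,2.613
Cu,60,1.593
Cu,80,0.7630
Cu,100,0.4584
Cu,150,0.2217
Cu,200,0.1559
Cu,300,0.1119
Cu,400,0.09413
Cu,500,0.08362
Cu,600,0.07625
Cu,800,0.06605
Cu,1000,0.05901
Cu,1250,0.05261
Cu,1500,0.04803
Cu,2000,0.04205
Cu,3000,0.03599
Cu,4000,0.03318
Cu,5000,0.03177
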