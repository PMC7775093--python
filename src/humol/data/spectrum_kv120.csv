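# Bundled example kVCT spectrum: 120 kVp Kramers bremsstrahlung
# filtered by 1.25 mm of copper (heavily filtered diagnostic beam),
# fluence-normalized. Weighted mean energy 78.1 keV.
energy_kev,weight
20.0,3.545459e-17
22.0,2.148942e-13
24.0,9.963337e-11
26.0,8.536811e-09
28.0,2.322206e-07
30.0,2.831498e-06
32.0,1.976789e-05
34.0,8.997371e-05
36.0,2.977224e-04
38.0,7.736961e-04
40.0,1.669536e-03
42.0,3.094957e-03
44.0,5.127111e-03
46.0,7.763325e-03
48.0,1.093181e-02
50.0,1.450873e-02
52.0,1.821211e-02
54.0,2.199177e-02
56.0,2.570689e-02
58.0,2.923600e-02
60.0,3.248175e-02
62.0,3.507799e-02
64.0,3.729059e-02
66.0,3.910030e-02
68.0,4.050203e-02
70.0,4.150184e-02
72.0,4.211414e-02
74.0,4.235931e-02
76.0,4.226172e-02
78.0,4.184808e-02
80.0,4.114619e-02
82.0,3.996460e-02
84.0,3.859302e-02
86.0,3.705386e-02
88.0,3.536801e-02
90.0,3.355483e-02
92.0,3.163215e-02
94.0,2.961621e-02
96.0,2.752183e-02
98.0,2.536238e-02
100.0,2.314995e-02
102.0,2.079525e-02
104.0,1.843895e-02
106.0,1.608588e-02
108.0,1.374028e-02
110.0,1.140584e-02
112.0,9.085795e-03
114.0,6.782941e-03
116.0,4.499692e-03
118.0,2.238121e-03
120.0,0.000000e+00
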