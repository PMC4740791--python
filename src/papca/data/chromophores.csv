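wavelength_nm,hemoglobin,lipid,collagen,water
680,0.35,0.004,0.004,0.002
690,0.327427,0.004,0.004,0.002
700,0.306311,0.004,0.004,0.002
710,0.286556,0.004,0.004,0.002
720,0.268075,0.004,0.004,0.002
730,0.250786,0.004,0.004,0.002
740,0.234612,0.004,0.004,0.002
750,0.219481,0.004,0.004,0.002
760,0.205326,0.004,0.004,0.002
770,0.192084,0.004,0.004,0.002
780,0.179696,0.004,0.004,0.002
790,0.168107,0.004,0.004,0.002
800,0.157265,0.004,0.004,0.002
810,0.147123,0.004,0.004,0.002
820,0.137634,0.004,0.004,0.002
830,0.128758,0.004,0.004,0.002
840,0.120454,0.004001,0.004,0.002
850,0.112685,0.004005,0.004,0.002
860,0.105418,0.004033,0.004,0.002001
870,0.098619,0.004167,0.004,0.002003
880,0.092259,0.004659,0.004,0.002015
890,0.086309,0.00603,0.004,0.00206
900,0.080743,0.00887,0.004,0.002198
910,0.075535,0.013098,0.004,0.002561
920,0.070664,0.017237,0.004,0.003353
930,0.066106,0.019,0.004,0.00478
940,0.061843,0.017237,0.004,0.006868
950,0.057855,0.013098,0.004,0.009261
1200,0.008678,0.114774,0.004,0.002425
1210,0.008678,0.124,0.004,0.002657
1220,0.008678,0.114774,0.004,0.002998
1230,0.008678,0.091138,0.004002,0.003489
1240,0.008678,0.06241,0.004008,0.004183
1250,0.008678,0.037365,0.004034,0.005142
1260,0.008678,0.020241,0.00412,0.006444
1270,0.008678,0.010739,0.004387,0.008175
1280,0.008678,0.006389,0.005111,0.010428
1290,0.008678,0.004741,0.006857,0.013301
1300,0.008678,0.004246,0.010573,0.016887
1310,0.008678,0.004193,0.017534,0.021264
1320,0.008678,0.004364,0.028936,0.02649
1330,0.008678,0.004779,0.045112,0.032584
1340,0.008678,0.005596,0.064655,0.039522
1350,0.008678,0.007076,0.084077,0.047222
1360,0.008678,0.009569,0.098601,0.055543
1370,0.008678,0.013473,0.104008,0.064277
1380,0.008678,0.019139,0.098609,0.07316
1390,0.008678,0.026726,0.084096,0.081876
1400,0.008678,0.036048,0.064688,0.090081
1410,0.008678,0.046457,0.045167,0.097417
1420,0.008678,0.056839,0.029023,0.103543
1430,0.008678,0.065775,0.017668,0.108158
1440,0.008678,0.071846,0.010776,0.111027
1450,0.008678,0.074,0.00716,0.112
1460,0.008678,0.071846,0.005555,0.111027
1470,0.008678,0.065775,0.005028,0.108158
1480,0.008678,0.056839,0.005032,0.103543
1490,0.008678,0.046457,0.005309,0.097417
1500,0.008678,0.036048,0.005766,0.090081
1510,0.008678,0.026726,0.006385,0.081876
1520,0.008678,0.019139,0.007183,0.07316
1530,0.008678,0.013473,0.008183,0.064277
1540,0.008678,0.009569,0.009413,0.055543
1550,0.008678,0.007076,0.010897,0.047222
1560,0.008678,0.005596,0.012651,0.039522
1570,0.008678,0.004778,0.014682,0.032584
1580,0.008678,0.004356,0.016986,0.02649
1590,0.008678,0.004153,0.019542,0.021264
1600,0.008678,0.004062,0.022313,0.016887
1610,0.008678,0.004023,0.025244,0.013301
1620,0.008678,0.004008,0.028261,0.010428
1630,0.008678,0.004003,0.031278,0.008175
1640,0.008678,0.004001,0.034194,0.006444
1650,0.008678,0.004,0.036903,0.005142
1660,0.008678,0.004,0.0393,0.004183
1670,0.008678,0.004,0.041284,0.003489
1680,0.008678,0.004,0.042769,0.002998
1690,0.008678,0.004,0.043689,0.002657
1700,0.008678,0.004,0.044,0.002425
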