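peak_id,rt_min,PW1_mean,PW1_sd,PW2_mean,PW2_sd,PW3_mean,PW3_sd,PW4_mean,PW4_sd,lcms_peak,compound,herb,wavelength_nm
A1,4.962,2998,163,17988,780,2752,479,18926,8759,9,Geniposidic acid,GF,254
A2,7.254,15782,1641,18086,6862,13959,2404,10340,823,11,6α-hydroxygeniposide,GF,254
A3,8.967,24376,1424,27308,1898,27651,1105,22305,7318,12,Gardenoside,GF,254
A4,10.061,20505,879,15073,846,20870,2052,11790,6655,15,6β-hydroxygeniposide,GF,254
A5,11.823,49745,6098,15921,4484,56507,3724,14876,4795,16,Picrocrocinic acid,GF,254
A6,13.955,10809,903,14132,1041,10797,503,13190,2380,17,Neochlorogenic acid,GF,254
A7,14.597,18657,1329,20724,1238,18376,1923,17596,6766,18,Chlorogenic acid,GF,254
A8,14.894,24057,325,15983,301,25893,1203,13543,3082,19,Protocatechuic acid,GF,254
A9,16.241,143447,4417,130510,8952,123082,5242,139748,12734,21,Genipin 1-gentiobioside,GF,254
A10,16.765,16423,2684,10798,452,20768,2332,9437,2839,22,Sinapyglucoside,GF,254
A11,17.226,695037,21423,721878,83827,733526,28076,765815,23316,23,Geniposide,GF,254
A12,18.698,29717,1712,28002,5245,31242,2196,19826,3424,26,Picrocrocin,GF,254
A13,19.001,36244,2202,37164,5195,36668,1079,22160,6734,27,Rutin-isomer,GF,254
A14,21.686,27327,2217,19686,1098,26387,1833,17373,2546,28,Carthamidin-7-O-glucuronide,SR,254
A15,22.244,47883,458,43550,3103,46438,734,42734,2201,30,Isoquercetin,SR,254
A16,22.547,50683,2540,48260,9111,46701,2784,42335,4867,31,Scutellarin,SR,254
A17,22.833,331651,25315,319402,4383,347312,21645,332529,19298,32,Chrysin 6-C-arabinoside 8-C-glucoside,SR,254
A18,24.98,226469,9668,226471,894,216251,1409,221335,10953,39,Chrysin 6-C-glucoside 8-C-arabinoside,SR,254
A19,25.814,50061,1477,50078,750,48010,608,49843,1839,42,Chrysin 6-C-glucoside 8-C-arabinoside isomer,SR,254
A20,25.978,51148,841,50401,1777,47781,1856,49468,1588,43,Trihydroxydihydrochalcone-3'-C-glucoside-6'-O-glucoside or isomer,SR,254
A21,27.985,18788,1294,16697,1579,17436,1206,16518,1077,51,Viscidulin III,SR,254
A22,29.152,70230,3907,65032,10918,69480,6047,64205,3446,54,Trihydroxy-methoxy-flavone-7-O-glucuronide,SR,254
A23,29.656,83912,1415,68058,2439,84110,1243,74256,4306,56,6''-O-[(E)-p-Coumaroyl] genipin gentiobioside or isomer,GF,254
A24,31.704,8378232,51287,8215389,176081,8394519,144070,8451971,50374,62,Baicalin,SR,254
A25,33.149,106929,5951,109616,2943,109496,6527,110777,3170,65,Dihydrobaicalin,SR,254
A26,34.949,492670,5428,473931,8798,490313,8622,503542,16936,67,Glychionide A,SR,254
A27,35.572,49090,2903,53118,1446,53056,2160,54830,925,69,Oroxylin A 7-O-D-glucuronide isomer,SR,254
A28,36.472,77953,2731,78722,1820,80404,1401,81515,5223,70,Norwogonin-8-O-glucuronide,SR,254
A29,37.135,111404,5959,107409,8274,112944,4394,111880,2683,71,"5,7,2'-Trihydroxy-6-methoxy-flavone-7-O-glucuronide",SR,254
A30,37.771,296565,6634,289719,6395,300501,8784,308742,4147,73,Chrysin-7-O-β-D-glucoronide,SR,254
A31,38.968,867803,29230,888166,24486,872761,42160,864701,13114,74,Oroxylin A-7-O-glucuronide,SR,254
A32,40.261,105809,2200,110273,8874,99396,4418,104173,10745,79,Kaempferol isomer,SR,254
A33,41.775,62715,1942,65939,7249,59428,4275,62811,9025,80,Baicalein-6-O-glucuronide,SR,254
A34,42.455,2251622,28194,2190797,53988,2233245,58642,2282152,67869,82,Wogonoside,SR,254
A35,44.474,42498,1119,42640,3159,44371,2629,42046,917,83,Norwogonin,SR,254
A36,45.96,14209,1530,14729,1838,13570,767,12786,755,89,Trihydroxymethoxy-flavone,SR,254
A37,46.389,40856,7758,44247,4859,46736,5216,42855,3390,90,Baicalein,SR,254
A38,50.852,11696,2652,13188,2256,13199,1046,12781,986,100,Wogonin,SR,254
A39,51.603,4568,492,7010,1566,5515,2092,4017,742,101,Chrysin,SR,254
A40,51.985,21862,2444,24841,4204,28551,3692,25328,1838,104,Oroxylin A,GF,254
B1,27.031,2699,66,0,0,3541,182,0,0,,Unknown,GF,440
B2,28.512,1826,61,0,0,2601,68,0,0,,Unknown,GF,440
B3,28.94,3641,364,0,0,4342,437,0,0,,Unknown,GF,440
B4,29.244,1153,82,0,0,1767,258,0,0,,Unknown,GF,440
B5,30.151,2760,105,0,0,3703,233,0,0,,Unknown,GF,440
B6,32.792,401421,17117,16607,3417,524700,35421,17248,1792,64,Crocin I,GF,440
B7,34.101,26276,1453,2689,583,27694,3188,2720,215,,Unknown,GF,440
B8,39.524,36900,2189,0,0,52355,3630,0,0,75,Crocin II,GF,440
B9,46.324,18539,1180,0,0,27214,4328,0,0,,Unknown,GF,440
B10,46.975,4724,529,0,0,6728,1108,0,0,,Unknown,GF,440
B11,48.756,21526,2832,18231,4940,31397,6500,23220,7320,95,all-trans-Crocetin di-β-D-glucosyl ester,GF,440
B12,49.487,87444,2497,6708,1673,107961,6890,7557,4119,96,Crocin I isomer,GF,440
B13,50.215,7982,301,0,0,8395,771,0,0,109,Neocrocin B/C/D/E,GF,440
B14,54.913,1633,253,2291,935,2374,744,3202,1171,110,Crocin-III or isomer 1,GF,440
B15,55.102,1173,92,0,0,1533,391,0,0,111,Crocin-III or isomer 2,GF,440
B16,55.627,2235,266,3165,1235,3114,947,4097,1285,112,Crocin-III or isomer 3,GF,440
B17,59.06,0,0,1193,421,0,0,1140,221,113,Crocetin,GF,440
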