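panchayat,lat,lon,kerma_k40,kerma_u238,kerma_th232,kerma_total,contrib_k40,contrib_u238,contrib_th232,activity_k40,activity_k40_err,activity_u238,activity_u238_err,activity_th232,activity_th232_err,surface
Alappad,9.0369,76.5087,4,159,471,634,1,25,74,99,2,359,22,716,29,soil
Alappad,9.0524,76.5068,10,25,69,104,10,24,66,240,5,57,3,105,4,soil
Alappad,9.1352,76.4639,28,16,47,91,31,17,52,672,13,36,2,71,3,soil
Chavara,8.9696,76.5361,1,55,198,254,1,22,78,32,1,124,7,300,12,soil
Chavara,8.9704,76.5450,2,95,334,431,0,22,77,44,1,215,13,507,20,soil
Chavara,8.9877,76.5616,9,24,58,91,10,26,64,214,4,54,3,88,4,soil
Chavara,8.9848,76.5527,4,41,92,137,3,30,67,92,2,93,6,142,6,grass
Chavara,8.9889,76.5314,2,46,166,214,1,21,78,46,1,103,6,253,10,soil
Chavara,8.9698,76.5294,17,163,461,641,3,25,72,407,8,370,22,709,28,soil
Chavara,8.9928,76.5242,40,558,1543,2141,2,26,72,955,19,1269,76,2374,95,sand
Neendakara,8.9680,76.5316,6,39,113,158,4,25,71,145,3,88,5,172,7,soil
Neendakara,8.9634,76.5317,6,98,220,324,2,30,68,151,3,222,13,334,13,soil
Neendakara,8.9557,76.5328,25,391,967,1383,2,28,70,594,12,889,53,1488,60,sand
Neendakara,8.9557,76.5328,40,521,1460,2021,2,26,72,964,19,1185,71,2247,90,sand
Neendakara,8.9534,76.5418,4,76,277,357,1,21,77,102,2,172,10,420,17,grass
Neendakara,8.9420,76.5360,5,125,430,560,1,22,77,113,2,283,17,654,26,sand
Oachira,9.1352,76.5281,6,28,70,104,6,27,67,139,3,64,4,107,4,soil
Oachira,9.1329,76.5338,3,11,28,42,8,26,66,81,2,25,2,42,2,soil
Oachira,9.1167,76.5293,3,18,52,73,4,25,71,66,1,41,2,79,3,soil
Oachira,9.1170,76.5180,2,22,66,90,2,25,73,37,1,51,3,100,4,soil
Oachira,9.1351,76.5088,2,61,215,278,1,22,77,56,1,138,8,327,13,soil
Panmana,9.0309,76.5501,10,105,322,437,2,24,74,232,5,238,14,496,20,soil
Panmana,9.0019,76.5429,2,69,269,340,1,20,79,53,1,156,9,408,16,soil
Panmana,9.0041,76.5365,4,28,74,106,3,26,70,84,2,64,4,114,5,soil
Panmana,9.0008,76.5254,9,93,244,346,3,27,70,218,4,212,13,375,15,soil
Panmana,9.0162,76.5340,6,37,117,160,4,23,73,135,3,84,5,177,7,soil
Panmana,9.0250,76.5378,1,54,185,240,0,23,77,22,0,123,7,281,11,soil
Thevalakkara,9.0177,76.5617,5,20,57,82,6,24,70,115,2,45,3,86,3,soil
Thevalakkara,9.0135,76.5881,5,30,93,128,4,24,73,108,2,68,4,142,6,soil
Thevalakkara,9.0106,76.5934,5,33,94,132,4,25,72,112,2,74,4,143,6,soil
Thevalakkara,9.0061,76.5909,2,27,92,121,1,23,76,36,1,62,4,139,6,soil
Thevalakkara,8.9920,76.5746,4,24,72,100,4,24,72,100,2,54,3,110,4,soil
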