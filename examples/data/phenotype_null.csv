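species,SVL,AG,AL,TbL,FL,PW
sp09,62.230586,16.499636,21.579011,22.197835,31.765791,35.605712
sp07,57.920524,19.546598,21.436542,23.213187,25.096807,42.5298
sp22,76.626479,33.70503,19.659639,37.301513,43.997783,47.370582
sp14,63.012297,24.569684,23.678773,25.201985,29.954155,39.857074
sp02,73.266156,28.825131,26.758924,31.957212,30.287973,43.051002
sp03,56.088586,20.454485,15.925659,23.097894,43.342921,33.802229
sp19,57.527305,21.014584,16.40051,23.685179,45.334025,34.354639
sp12,57.91873,14.322915,24.580682,19.176733,35.97886,37.636244
sp08,59.24976,15.255746,22.546861,18.920129,33.896556,41.074084
sp20,62.066962,16.017969,27.831891,24.299715,23.509599,35.850306
sp18,84.824256,33.739837,28.707854,40.523735,55.67491,61.724455
sp11,77.642777,29.305245,27.718953,37.311423,51.826141,47.086058
sp04,77.535143,30.864858,25.464551,29.460548,29.755746,59.185068
sp26,62.767239,27.192654,19.12708,20.665273,24.174734,51.480669
sp15,50.680642,12.509891,19.769371,14.456847,22.053376,47.055118
sp01,67.812866,25.969297,13.922119,21.963872,32.977505,50.763899
sp05,66.622369,21.608948,19.39306,18.851864,29.520289,41.371379
sp13,62.477294,33.068369,25.656406,23.571486,26.670021,63.120675
sp24,33.339533,15.301326,17.000709,14.061038,13.288421,25.617201
sp16,44.5789,15.21548,17.241479,28.70236,25.160393,21.335827
sp10,46.944503,18.185829,22.64423,21.222398,31.724123,20.340991
sp25,52.758803,21.726597,18.284287,30.279185,38.954135,38.70768
sp17,65.011735,26.224156,27.601587,43.855392,54.184059,35.517444
sp21,57.488276,31.406107,30.717136,27.053942,23.201557,22.544924
sp23,42.226753,26.005251,21.722241,24.72874,12.234888,17.426886
sp06,45.695492,28.001644,20.180819,31.435078,12.915667,13.243825
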