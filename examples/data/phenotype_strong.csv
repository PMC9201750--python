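species,SVL,AG,AL,TbL,FL,PW
sp09,62.230586,20.413708,26.698022,27.463644,39.301328,44.052162
sp07,57.920524,29.705537,32.57774,35.27776,38.140353,64.633783
sp22,76.626479,32.363251,18.876999,35.816561,42.246256,45.484785
sp14,63.012297,25.303827,24.386295,25.955021,30.849186,41.048004
sp02,73.266156,27.242653,25.28988,30.202785,28.625186,40.687535
sp03,56.088586,23.329206,18.163888,26.344125,49.434434,38.552871
sp19,57.527305,23.964274,18.70255,27.009724,51.697286,39.17679
sp12,57.91873,14.263409,24.478559,19.097062,35.829383,37.479882
sp08,59.24976,14.645226,21.644557,18.162963,32.540048,39.430338
sp20,62.066962,18.954322,32.933926,28.754245,27.819288,42.422246
sp18,84.824256,31.88465,27.129351,38.295536,52.613622,58.330532
sp11,77.642777,28.977119,27.408589,36.893654,51.245852,46.558843
sp04,77.535143,28.185488,23.253981,26.903086,27.172659,54.047229
sp26,62.767239,27.63198,19.436098,20.999142,24.565302,52.312392
sp15,50.680642,13.268107,20.967579,15.333067,23.390016,49.907097
sp01,67.812866,27.268189,14.618454,23.062426,34.626922,53.302928
sp05,66.622369,24.766418,22.226748,21.606473,33.833753,47.416508
sp13,62.477294,38.522811,29.888286,27.45947,31.069091,73.532075
sp24,33.339533,16.094773,17.882276,14.79017,13.977489,26.945575
sp16,44.5789,14.754191,16.718769,27.832189,24.397604,20.688988
sp10,46.944503,17.313802,21.558419,20.204765,30.202923,19.365622
sp25,52.758803,22.088403,18.58877,30.783415,39.602827,39.352267
sp17,65.011735,24.4948,25.781396,40.963341,50.610883,33.17524
sp21,57.488276,29.179357,28.539235,25.135768,21.556524,20.946447
sp23,42.226753,21.882545,18.278536,20.808404,10.295247,14.664139
sp06,45.695492,24.770718,17.852287,27.807991,11.425413,11.715707
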