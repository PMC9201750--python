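species,SVL,AG,AL,TbL,FL,PW
sp09,62.230586,18.352623,24.002436,24.690756,35.333239,39.604401
sp07,57.920524,24.096518,26.42639,28.616591,30.938667,52.42959
sp22,76.626479,33.027327,19.264345,36.551497,43.113125,46.418108
sp14,63.012297,24.934054,24.029931,25.575731,30.398376,40.448156
sp02,73.266156,28.022724,26.014034,31.067617,29.444845,41.852588
sp03,56.088586,21.844608,17.007995,24.667668,46.288581,36.099487
sp19,57.527305,22.441017,17.513748,25.292887,48.411218,36.686571
sp12,57.91873,14.293131,24.529567,19.136856,35.904043,37.557982
sp08,59.24976,14.947369,22.091103,18.537681,33.211377,40.24382
sp20,62.066962,17.424401,30.275625,26.433312,25.573821,38.998083
sp18,84.824256,32.799129,27.907444,39.393885,54.122626,60.003502
sp11,77.642777,29.14072,27.563334,37.10195,51.53518,46.821709
sp04,77.535143,29.494764,24.334178,28.152791,28.434886,56.557837
sp26,62.767239,27.411437,19.28097,20.831539,24.369236,51.894864
sp15,50.680642,12.883422,20.359663,14.888512,22.711865,48.460131
sp01,67.812866,26.610819,14.266038,22.506447,33.792151,52.017924
sp05,66.622369,23.133876,20.761615,20.182227,31.603515,44.290928
sp13,62.477294,35.691547,27.691623,25.441315,28.785644,68.127779
sp24,33.339533,15.693036,17.435922,14.420996,13.628601,26.272994
sp16,44.5789,14.98306,16.978113,28.263926,24.776063,21.009918
sp10,46.944503,17.744459,22.094656,20.707331,30.95418,19.847316
sp25,52.758803,21.906753,18.4359,30.530259,39.277142,39.028643
sp17,65.011735,25.344732,26.675971,42.384707,52.367004,34.326371
sp21,57.488276,30.272265,29.608167,26.077224,22.36392,21.730993
sp23,42.226753,23.855001,19.926133,22.684039,11.223243,15.98594
sp06,45.695492,26.336682,18.980879,29.565966,12.147708,12.456355
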