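species,vegetation_PC1,vegetation_PC2,vegetation_PC3,temperature_PC1,temperature_PC2,precipitation_PC1,precipitation_PC2,elevation
sp09,2.128683,-2.707069,1.697841,-2.763209,0.255196,0.074075,0.146943,0.532528
sp07,4.185322,-2.537585,1.860744,-2.890803,-0.0347,1.108548,0.334522,1.759098
sp22,-0.406235,-2.07998,4.097396,-0.071349,0.034974,1.099887,-1.0188,-0.837033
sp14,0.294423,-1.044257,4.342907,0.440317,-0.200946,1.318862,-1.080981,-0.054545
sp02,-0.564637,-1.923048,3.955443,1.23105,-0.391082,1.481428,-0.185479,0.217093
sp03,1.315038,-3.55534,3.443563,-0.989278,-0.521731,1.870043,-1.181861,-0.70944
sp19,1.313474,-3.403593,3.40891,-0.94233,-0.582031,1.817188,-1.183867,-0.771529
sp12,-0.041632,-2.446735,1.547003,0.345456,-0.528458,1.512185,0.502626,0.877057
sp08,-0.408418,-3.086734,1.779562,0.372525,-0.828132,0.880945,1.185781,-0.57892
sp20,1.683208,-2.282348,2.866318,1.292382,-1.426917,1.220046,0.094633,0.336088
sp18,-0.565545,-0.747598,2.547571,-1.628694,0.93758,-1.266507,-1.387331,-1.806274
sp11,-0.1126,-0.643241,2.242608,-1.576576,1.144727,-1.906178,-0.873266,-1.928225
sp04,-0.90811,-0.191203,0.184642,1.787617,1.180284,0.428516,0.490154,-0.056327
sp26,0.160269,-1.031996,0.30442,0.591593,0.978378,-0.738736,-2.245544,-0.707943
sp15,0.588436,-0.364647,0.913601,-1.739012,-0.026846,-0.220541,-0.988748,-0.92038
sp01,0.488058,-2.746856,-2.134571,-1.087713,-0.63537,-0.56368,-0.7954,-0.889348
sp05,1.363811,-1.054435,-0.762264,-1.532282,-0.454295,-0.597582,-2.638094,0.226607
sp13,1.526733,-0.521386,-4.096908,0.434025,-4.439499,0.199284,1.237081,-3.620608
sp24,0.505551,1.299767,-3.028788,1.755797,-3.172253,-0.183687,-2.078261,-0.238828
sp16,-0.307861,1.176545,-1.801566,0.039676,-0.492443,-0.204539,-1.53254,0.703965
sp10,-0.491387,0.015768,-1.836556,2.787027,1.863977,0.2662,1.423464,-1.86282
sp25,0.165156,2.042922,-0.184964,0.675974,1.434035,-1.570066,-2.017794,-0.13359
sp17,-0.682201,-0.207042,0.760951,0.635062,-0.174371,1.173551,-3.188825,-0.911507
sp21,-0.735409,-3.418699,2.746475,-1.131309,-0.726624,1.529876,-0.564646,-1.853405
sp23,-1.726092,-1.477829,1.172035,0.232896,-0.127244,-0.094205,-2.891196,-0.97867
sp06,-1.22601,-1.923286,1.360254,2.305808,-0.960632,-0.253767,-2.628316,-0.531428
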