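T_K,P_bar,rho_kg_m3,y2,s_g_L
308,120,769,0.0304e-4,0.0231
308,150,817,0.0434e-4,0.035
308,180,849,0.0592e-4,0.0497
308,210,875,0.1087e-4,0.0939
308,240,896,0.1231e-4,0.1088
308,270,914,0.1459e-4,0.1316
318,120,661,0.0627e-4,0.0409
318,150,744,0.1098e-4,0.0806
318,180,791,0.1406e-4,0.1097
318,210,824,0.2029e-4,0.165
318,240,851,0.2498e-4,0.2097
318,270,872,0.3158e-4,0.2718
328,120,509,0.0982e-4,0.0494
328,150,656,0.1591e-4,0.1029
328,180,725,0.197e-4,0.1409
328,210,769,0.2731e-4,0.2072
328,240,802,0.3154e-4,0.2496
328,270,829,0.4351e-4,0.3557
338,120,388,0.1398e-4,0.0534
338,150,557,0.2297e-4,0.1263
338,180,652,0.2822e-4,0.1816
338,210,710,0.3299e-4,0.2312
338,240,751,0.3921e-4,0.2906
338,270,783,0.5515e-4,0.4262
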