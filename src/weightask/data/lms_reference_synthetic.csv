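sex,agemos,L,M,S
male,156,-2.200,18.500,0.1250
male,162,-2.179,18.737,0.1259
male,168,-2.157,18.984,0.1267
male,174,-2.136,19.240,0.1276
male,180,-2.114,19.505,0.1284
male,186,-2.093,19.779,0.1293
male,192,-2.071,20.062,0.1301
male,198,-2.050,20.355,0.1310
male,204,-2.029,20.657,0.1319
male,210,-2.007,20.968,0.1327
male,216,-1.986,21.288,0.1336
male,222,-1.964,21.617,0.1344
male,228,-1.943,21.956,0.1353
male,234,-1.921,22.303,0.1361
male,240,-1.900,22.660,0.1370
female,156,-2.100,18.900,0.1350
female,162,-2.082,19.004,0.1357
female,168,-2.064,19.123,0.1364
female,174,-2.046,19.256,0.1371
female,180,-2.029,19.403,0.1379
female,186,-2.011,19.564,0.1386
female,192,-1.993,19.740,0.1393
female,198,-1.975,19.930,0.1400
female,204,-1.957,20.134,0.1407
female,210,-1.939,20.353,0.1414
female,216,-1.921,20.586,0.1421
female,222,-1.904,20.833,0.1429
female,228,-1.886,21.094,0.1436
female,234,-1.868,21.370,0.1443
female,240,-1.850,21.660,0.1450
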