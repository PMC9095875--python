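temperature_K,pressure_MPa,density_kg_m3,mole_fraction,solubility_g_L,std_dev,expanded_U
308,12,769,0.0648e-4,0.0435,0.001e-4,0.0036e-4
308,15,817,0.0764e-4,0.0544,0.003e-4,0.0069e-4
308,18,849,0.0921e-4,0.0682,0.004e-4,0.0090e-4
308,21,875,0.0958e-4,0.0731,0.004e-4,0.0091e-4
308,24,896,0.1239e-4,0.0968,0.006e-4,0.0132e-4
308,27,914,0.1489e-4,0.1183,0.006e-4,0.0137e-4
318,12,661,0.0548e-4,0.0316,0.002e-4,0.0047e-4
318,15,744,0.0580e-4,0.0377,0.002e-4,0.0048e-4
318,18,791,0.0990e-4,0.0682,0.004e-4,0.0091e-4
318,21,824,0.1192e-4,0.0856,0.003e-4,0.0080e-4
318,24,851,0.1436e-4,0.1064,0.004e-4,0.0102e-4
318,27,872,0.1930e-4,0.1467,0.007e-4,0.0164e-4
328,12,509,0.0381e-4,0.0170,0.001e-4,0.0026e-4
328,15,656,0.0498e-4,0.0285,0.001e-4,0.0030e-4
328,18,725,0.1388e-4,0.0877,0.003e-4,0.0086e-4
328,21,769,0.1579e-4,0.1059,0.004e-4,0.0106e-4
328,24,802,0.2354e-4,0.1646,0.003e-4,0.0120e-4
328,27,829,0.3106e-4,0.2243,0.005e-4,0.0170e-4
338,12,388,0.0301e-4,0.0101,0.001e-4,0.0024e-4
338,15,557,0.0403e-4,0.0196,0.002e-4,0.0044e-4
338,18,652,0.1548e-4,0.0880,0.002e-4,0.0080e-4
338,21,710,0.1938e-4,0.1200,0.004e-4,0.0118e-4
338,24,751,0.3408e-4,0.2231,0.006e-4,0.0192e-4
338,27,783,0.4634e-4,0.3163,0.003e-4,0.0213e-4
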