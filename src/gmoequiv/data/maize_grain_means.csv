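analyte,gm_counterpart,gm_gmo,gm_reference,var_genotype,var_site,var_block,var_residual
16:0 Palmitic,0.396,0.409,0.296,0.01573,0.003597,0,0.003831
16:1 Palmitoleic,0.004,0.004,0.004,0.00982,0,0.000873,0.003754
18:0 Stearic,0.047,0.047,0.056,0.0274,0.000701,0.000814,0.00554
18:1 Oleic,0.871,0.935,0.812,0.03305,0.000298,0.000307,0.003484
18:2 Linoleic,1.512,1.492,1.675,0.01189,0.002407,0.000909,0.004923
18:3 Linolenic,0.034,0.031,0.034,0.01336,0.003134,0.00088,0.004658
20:0 Arachidic,0.013,0.013,0.013,0.01037,0.001517,0.000802,0.003484
20:1 Eicosenoic,0.011,0.011,0.01,0.01846,0.003502,0.000642,0.005708
22:0 Behenic,0.005,0.005,0.005,0.01075,0.002956,0.00046,0.002557
Acid detergent fiber,3.52,3.884,3.523,0.0071,0.000355,0,0.027063
Alanine,6.172,6.366,6.999,0.01215,0.001757,0.001137,0.001974
Arginine,3.641,3.816,4.153,0.00264,0.00029,0.000318,0.002505
Ash,1.13,1.167,1.27,0,0.005899,0.000455,0.010976
Aspartic acid,5.281,5.453,5.967,0.00774,0.000515,0.000592,0.001391
Calcium,51.015,49.108,42.441,0.02556,0.012244,0,0.004253
Carbohydrates,75.683,75.084,74.458,0.00006,0.000177,6E-07,0.000041
Copper,1.161,1.242,1.322,0.03896,0,0,0.009164
Cystine,1.699,1.689,1.819,0.00544,0.000305,0.001014,0.001862
Ferulic acid,2008,1747,1841,0.01331,0.00426,0.000544,0.008106
Folic acid,0.543,0.618,0.573,0.01341,0,0.001377,0.079694
Glutamic acid,15.536,16.056,17.57,0.01474,0.001769,0.00147,0.00226
Glycine,3.063,3.172,3.395,0.00243,0.00023,0.00041,0.001327
Histidine,2.389,2.452,2.63,0.00656,0,0.000705,0.001949
Iron,17.11,16.539,18.846,0.01445,0.01215,0,0.009386
Isoleucine,2.747,2.869,3.088,0.01289,0.000131,0.00151,0.00289
Leucine,10.231,10.562,11.57,0.01851,0.004143,0.001788,0.002688
Lysine,2.602,2.715,2.925,0.00074,0.00018,0,0.002259
Magnesium,1060,1104,1144,0.00672,0.000345,0.000045,0.001882
Manganese,6.377,6.705,6.67,0.03391,0.002448,0.000885,0.003924
Methionine,1.767,1.718,1.889,0.01255,0.001974,0.001786,0.003079
Moisture,11.94,12.093,11.973,0.00098,0.007057,0,0.000693
Neutral detergent fiber,8.629,9.826,9.166,0.00409,0.00175,0.001613,0.015329
Niacin,18.241,15.9,20.915,0.01264,0.002064,0.000351,0.002513
p-coumaric acid,154.5,147.9,165.5,0.05678,0.00603,3.46E-05,0.011303
Phenylalanine,4.102,4.255,4.631,0.0145,0.002208,0.001255,0.001975
Phosphorus,2799,2804,3177,0.00427,0.002569,0,0.002005
Phytic acid,0.57,0.523,0.658,0,0.000268,0.009507,0.031919
Potassium,3242,3171,3604,0.00313,0.008,0,0.001503
Proline,7.29,7.69,7.997,0.01372,0,0.002004,0.002592
Protein,8.222,8.449,9.132,0.00878,0.000437,0.000713,0.001314
Raffinose,0.113,0.118,0.09,0.04279,0.017792,0,0.028393
Serine,4.119,4.242,4.628,0.00901,0.003357,0.00139,0.002331
Threonine,2.724,2.858,3.046,0.00621,0,0.000773,0.002362
Total dietary fiber,11.448,12.801,12.301,0.00545,0.00252,0.000949,0.015822
Total fat,2.979,3.138,3.038,0.01024,0.001744,0.000382,0.002228
Tryptophan,0.481,0.505,0.543,0.00176,0.000333,0.000318,0.004406
Tyrosine,2.674,2.768,3.152,0.01124,0.003216,0.000612,0.01474
Valine,3.739,3.902,4.239,0.00793,0,0.000922,0.002064
Vitamin B1,0.344,0.352,0.352,0.00844,0.00015,0.000611,0.003195
Vitamin B2,1.177,1.103,1.221,0.00269,0.018009,0,0.007777
Vitamin B6,4.736,4.723,5.764,0.00946,0.009281,0.000296,0.002828
Vitamin E,0.006,0.006,0.009,0.02613,0.000318,0.000115,0.009676
Zinc,19.535,19.111,21.338,0.0136,0.001851,0.000192,0.003364
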