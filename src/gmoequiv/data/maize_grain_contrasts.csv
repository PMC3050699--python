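analyte,ratio_gc,dlow,dupp,sed_gc1,df_gc1,ratio_gr,elow,eupp,sed_gr2,df_gr2
16:0 Palmitic,1.034,0.9887,1.081,0.02658,49.3,1.3811,1.0317,1.849,0.1317,10.5
16:1 Palmitoleic,0.999,0.9558,1.045,0.02638,38.7,0.9982,0.7841,1.271,0.1055,8.4
18:0 Stearic,1.008,0.9538,1.066,0.03307,41.7,0.8355,0.57,1.225,0.1736,10.9
18:1 Oleic,1.074,1.0294,1.121,0.02538,42.1,1.1519,0.7595,1.747,0.1897,11.2
18:2 Linoleic,0.987,0.9366,1.04,0.03121,42.2,0.8908,0.6886,1.152,0.1155,10
18:3 Linolenic,0.904,0.8606,0.95,0.02942,39.9,0.9234,0.7009,1.216,0.1221,9.1
20:0 Arachidic,1.034,0.9906,1.079,0.02545,41.5,0.9931,0.7816,1.262,0.1075,10
20:1 Eicosenoic,0.995,0.9419,1.051,0.03253,41.4,1.11,0.8068,1.527,0.1432,10
22:0 Behenic,0.946,0.9117,0.981,0.0218,41.4,0.9766,0.7672,1.243,0.1089,10.4
Acid detergent fiber,1.103,0.9805,1.241,0.07046,51.9,1.1026,0.8373,1.452,0.1027,4.4
Alanine,1.031,0.9986,1.065,0.0192,41.4,0.9096,0.7052,1.173,0.1154,10.8
Arginine,1.048,1.0107,1.087,0.02153,41.9,0.9188,0.8077,1.045,0.0558,7.9
Ash,1.033,0.958,1.114,0.04498,54.6,0.9187,0.858,0.984,0.0341,53.6
Aspartic acid,1.033,1.0049,1.061,0.0161,41.4,0.9138,0.7455,1.12,0.0921,10.7
Calcium,0.963,0.9184,1.009,0.02801,48.5,1.1571,0.7993,1.675,0.1673,10.6
Carbohydrates,0.992,0.9875,0.997,0.00274,42,1.0084,0.9895,1.028,0.0083,8.2
Copper,1.069,0.9963,1.148,0.04221,51,0.9395,0.5947,1.484,0.2073,10.8
Cystine,0.994,0.9636,1.026,0.01863,40.1,0.9286,0.7797,1.106,0.0779,9.5
Ferulic acid,0.87,0.8132,0.931,0.04008,41.8,0.9489,0.7179,1.254,0.1234,9
Folic acid,1.138,0.929,1.395,0.12096,44.1,1.0786,0.6948,1.674,0.1515,3.6
Glutamic acid,1.033,0.9984,1.07,0.02055,41.4,0.9138,0.6908,1.209,0.127,10.9
Glycine,1.035,1.0084,1.063,0.01571,40.2,0.9343,0.8292,1.053,0.0525,8.8
Histidine,1.026,0.994,1.06,0.01903,40.7,0.9325,0.7711,1.128,0.0853,10
Iron,0.967,0.9015,1.036,0.04159,49.4,0.8776,0.6544,1.177,0.1288,8.6
Isoleucine,1.044,1.0045,1.086,0.0232,41.6,0.9292,0.7137,1.21,0.1192,10.5
Leucine,1.032,0.9942,1.072,0.02241,41.3,0.9129,0.6673,1.249,0.1422,10.9
Lysine,1.043,1.0084,1.08,0.02037,48.8,0.9282,0.8532,1.01,0.0322,4.7
Magnesium,1.041,1.0089,1.074,0.01863,42.6,0.9647,0.796,1.169,0.0863,10
Manganese,1.051,1.0047,1.1,0.02702,41.1,1.0053,0.6585,1.535,0.1922,11
Methionine,0.972,0.9338,1.012,0.02398,41.1,0.9095,0.7004,1.181,0.1177,10.3
Moisture,1.013,0.9938,1.032,0.0113,49.5,1.01,0.9357,1.09,0.0336,8.6
Neutral detergent fiber,1.139,1.0413,1.245,0.05322,43.2,1.072,0.8703,1.32,0.0778,4.4
Niacin,0.872,0.8405,0.904,0.0216,41.7,0.7602,0.5862,0.986,0.1178,10.8
p-coumaric acid,0.957,0.8867,1.034,0.04565,42.1,0.8938,0.5145,1.553,0.2498,10.6
Phenylalanine,1.037,1.0043,1.071,0.01921,41.4,0.9187,0.6965,1.212,0.1258,11
Phosphorus,1.002,0.9698,1.034,0.01923,48.5,0.8823,0.7537,1.033,0.0694,8.8
Phytic acid,0.919,0.8042,1.049,0.07949,53.2,0.7958,0.7082,0.894,0.0581,52.2
Potassium,0.978,0.9509,1.006,0.01665,47.9,0.8798,0.7675,1.009,0.0595,8.2
Proline,1.055,1.0166,1.095,0.02199,41.9,0.9616,0.7333,1.261,0.1227,10.7
Protein,1.028,1.001,1.055,0.01566,41.2,0.9252,0.7454,1.148,0.098,10.8
Raffinose,1.036,0.9177,1.17,0.07232,49.1,1.3123,0.7939,2.169,0.2218,8.9
Serine,1.03,0.9944,1.067,0.02087,41.1,0.9167,0.7343,1.144,0.0998,10.2
Threonine,1.049,1.0131,1.087,0.02094,41.5,0.9383,0.7788,1.13,0.0834,9.8
Total dietary fiber,1.118,1.0211,1.225,0.05404,41.2,1.0407,0.8284,1.307,0.087,4.7
Total fat,1.054,1.0181,1.09,0.02035,41.9,1.033,0.8173,1.306,0.1062,10.8
Tryptophan,1.049,1.0002,1.101,0.02851,44,0.9292,0.8205,1.052,0.0487,5.1
Tyrosine,1.035,0.9483,1.13,0.05215,44.4,0.8782,0.6674,1.156,0.117,7.3
Valine,1.043,1.0096,1.078,0.0196,41.8,0.9203,0.7477,1.133,0.0936,10.3
Vitamin B1,1.023,0.9818,1.065,0.02433,43.3,0.9999,0.8059,1.241,0.0972,10.3
Vitamin B2,0.938,0.8799,0.999,0.03784,49,0.9036,0.7671,1.064,0.0611,4.4
Vitamin B6,0.997,0.9597,1.037,0.0229,41.6,0.8194,0.6529,1.028,0.1025,10.4
Vitamin E,0.953,0.8874,1.023,0.04217,42.5,0.6908,0.4718,1.011,0.1709,9.9
Zinc,0.978,0.9381,1.02,0.02495,42.5,0.8956,0.6814,1.177,0.1225,9.9
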