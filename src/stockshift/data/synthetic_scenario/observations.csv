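# synthetic data, stockshift generator v0.1.0, seed 20160101
# per-capture records for the two-partition feeding-ground study
id,year,scl_cm,haplotype
T0000,2006,61.0,H06
T0001,2007,63.2,H09
T0002,2007,51.4,H10
T0003,2007,69.4,H10
T0004,2007,41.6,H10
T0005,2007,45.1,H06
T0006,2007,34.0,H03
T0007,2007,66.6,H12
T0008,2006,31.9,H10
T0009,2007,63.0,H05
T0010,2007,57.5,H05
T0011,2006,54.3,H10
T0012,2007,68.9,H03
T0013,2007,43.7,H02
T0014,2007,52.8,H02
T0015,2007,68.5,H10
T0016,2006,50.0,H10
T0017,2007,55.5,H02
T0018,2007,55.3,H04
T0019,2006,67.7,H02
T0020,2007,70.8,H04
T0021,2006,74.8,H02
T0022,2007,71.8,H07
T0023,2007,66.5,H06
T0024,2006,53.1,H02
T0025,2007,63.9,H04
T0026,2007,55.8,H05
T0027,2006,43.1,H06
T0028,2006,49.5,H03
T0029,2006,63.1,H06
T0030,2007,40.4,H03
T0031,2006,40.2,H05
T0032,2006,49.0,H02
T0033,2007,48.0,H10
T0034,2006,38.7,H10
T0035,2007,60.0,H04
T0036,2006,41.3,H05
T0037,2007,57.0,H02
T0038,2007,35.5,H04
T0039,2006,43.3,H04
T0040,2006,35.9,H04
T0041,2007,55.5,H09
T0042,2007,53.5,H06
T0043,2007,30.3,H02
T0044,2007,42.0,H04
T0045,2006,47.4,H02
T0046,2006,38.3,H10
T0047,2007,59.5,H10
T0048,2007,59.8,H04
T0049,2006,30.5,H03
T0050,2007,64.8,H04
T0051,2007,39.3,H05
T0052,2007,42.3,H10
T0053,2007,43.9,H09
T0054,2007,43.4,H05
T0055,2006,39.2,H04
T0056,2006,50.5,H11
T0057,2007,65.1,H06
T0058,2006,32.8,H03
T0059,2006,41.5,H03
T0060,2006,71.6,H03
T0061,2006,74.5,H04
T0062,2006,69.2,H05
T0063,2007,67.6,H04
T0064,2006,34.9,H02
T0065,2006,37.3,H09
T0066,2007,36.2,H02
T0067,2007,56.7,H10
T0068,2006,52.6,H10
T0069,2007,41.6,H04
T0070,2006,70.9,H10
T0071,2006,65.3,H03
T0072,2007,51.2,H06
T0073,2007,67.5,H10
T0074,2006,67.6,H02
T0075,2007,43.6,H08
T0076,2006,55.1,H12
T0077,2006,63.8,H04
T0078,2006,69.8,H06
T0079,2006,36.0,H06
T0080,2007,55.8,H12
T0081,2006,59.6,H10
T0082,2006,45.8,H10
T0083,2006,42.4,H02
T0084,2006,67.4,H02
T0085,2006,60.9,H07
T0086,2007,36.6,H05
T0087,2006,33.3,H04
T0088,2006,38.8,H11
T0089,2007,39.2,H02
T0090,2006,33.0,H04
T0091,2007,59.0,H05
T0092,2007,60.7,H05
T0093,2007,51.6,H09
T0094,2007,56.9,H05
T0095,2007,48.3,H12
T0096,2006,40.8,H02
T0097,2006,37.1,H10
T0098,2007,66.2,H10
T0099,2006,62.6,H03
T0100,2007,67.6,H02
T0101,2007,48.8,H06
T0102,2007,40.8,H03
T0103,2006,32.0,H04
T0104,2007,60.5,H03
T0105,2007,69.4,H08
T0106,2007,44.5,H11
T0107,2007,45.6,H10
T0108,2006,57.6,H03
T0109,2006,31.4,H03
T0110,2007,68.9,H06
T0111,2007,68.4,H05
T0112,2007,34.8,H07
T0113,2007,34.9,H06
T0114,2006,72.7,H04
T0115,2007,43.1,H05
T0116,2007,42.7,H03
T0117,2007,64.4,H09
T0118,2006,38.5,H06
T0119,2007,46.8,H05
T0120,2016,36.2,H12
T0121,2015,49.1,H06
T0122,2015,54.4,H10
T0123,2016,51.1,H04
T0124,2016,66.5,H09
T0125,2016,64.3,H12
T0126,2015,40.4,H06
T0127,2016,52.7,H01
T0128,2015,53.6,H12
T0129,2016,46.8,H06
T0130,2016,64.5,H12
T0131,2016,59.4,H06
T0132,2016,54.9,H10
T0133,2016,45.8,H10
T0134,2015,54.4,H04
T0135,2016,62.6,H06
T0136,2016,59.0,H12
T0137,2016,64.8,H04
T0138,2016,61.8,H04
T0139,2016,42.9,H06
T0140,2016,71.1,H05
T0141,2015,70.3,H06
T0142,2016,40.3,H04
T0143,2015,67.7,H04
T0144,2015,31.2,H04
T0145,2016,53.2,H05
T0146,2015,50.1,H10
T0147,2015,31.2,H10
T0148,2016,62.1,H08
T0149,2015,30.3,H04
T0150,2015,53.5,H05
T0151,2016,73.5,H09
T0152,2015,47.0,H05
T0153,2015,68.8,H03
T0154,2015,74.3,H04
T0155,2016,37.9,H10
T0156,2016,43.1,H06
T0157,2015,43.0,H04
T0158,2015,54.2,H12
T0159,2016,62.4,H04
T0160,2016,36.8,H08
T0161,2015,65.4,H03
T0162,2015,71.4,H04
T0163,2015,46.6,H05
T0164,2016,54.5,H06
T0165,2016,34.6,H04
T0166,2016,32.2,H03
T0167,2015,39.8,H12
T0168,2016,36.0,H03
T0169,2016,40.0,H06
T0170,2016,31.9,H05
T0171,2016,67.4,H06
T0172,2015,65.7,H04
T0173,2015,41.1,H12
T0174,2016,57.4,H04
T0175,2016,32.8,H04
T0176,2016,66.6,H04
T0177,2015,72.3,H03
T0178,2016,62.6,H06
T0179,2016,39.2,H09
T0180,2015,68.4,H03
T0181,2015,38.7,H05
T0182,2015,60.3,H06
T0183,2015,39.4,H12
T0184,2015,45.0,H12
T0185,2015,31.3,H02
T0186,2016,68.4,H10
T0187,2015,43.9,H04
T0188,2015,74.8,H10
T0189,2016,67.4,H12
T0190,2016,45.6,H05
T0191,2015,48.6,H04
T0192,2015,32.2,H10
T0193,2016,45.6,H06
T0194,2016,53.0,H02
T0195,2016,39.6,H10
T0196,2016,45.1,H02
T0197,2015,48.5,H12
T0198,2016,61.0,H04
T0199,2015,39.5,H09
T0200,2015,32.9,H06
T0201,2015,52.3,H02
T0202,2016,68.1,H12
T0203,2016,54.5,H04
T0204,2016,61.4,H03
T0205,2015,35.9,H12
T0206,2015,34.1,H10
T0207,2015,47.0,H12
T0208,2016,48.8,H07
T0209,2016,34.7,H03
T0210,2015,32.6,H09
T0211,2016,51.2,H04
T0212,2016,65.3,H06
T0213,2016,32.8,H12
T0214,2016,43.9,H05
T0215,2015,32.9,H12
T0216,2016,32.4,H06
T0217,2015,70.4,H03
T0218,2015,63.6,H04
T0219,2015,73.0,H03
T0220,2016,66.1,H07
T0221,2016,46.1,H06
T0222,2015,35.2,H12
T0223,2016,34.1,H04
T0224,2015,46.7,H04
T0225,2015,32.1,H12
T0226,2016,40.5,H05
T0227,2015,32.4,H04
T0228,2015,49.0,H04
T0229,2016,35.8,H12
T0230,2015,30.4,H04
T0231,2016,60.8,H04
T0232,2016,42.2,H03
T0233,2016,62.0,H07
T0234,2016,74.5,H12
T0235,2015,50.6,H04
T0236,2015,68.6,H04
T0237,2015,69.2,H05
T0238,2015,69.8,H02
T0239,2015,59.1,H02
T0240,2016,60.3,H06
T0241,2016,35.6,H09
T0242,2015,41.2,H03
T0243,2015,50.0,H10
T0244,2016,67.5,H04
T0245,2016,52.9,H04
T0246,2016,67.1,H10
T0247,2015,66.5,H06
T0248,2016,30.3,H06
T0249,2015,65.0,H05
T0250,2015,73.3,H05
T0251,2015,58.9,H06
T0252,2015,72.2,H10
T0253,2016,63.0,H12
T0254,2016,47.4,H06
T0255,2016,45.2,H04
T0256,2015,40.2,H05
T0257,2016,41.6,H04
T0258,2015,36.1,H07
T0259,2016,71.3,H09
T0260,2015,68.7,H07
T0261,2016,63.5,H06
T0262,2015,46.7,H06
T0263,2015,44.4,H12
T0264,2016,53.7,H06
T0265,2015,60.1,H05
T0266,2015,47.1,H06
T0267,2015,69.8,H10
T0268,2016,41.0,H04
T0269,2016,55.9,H06
T0270,2015,71.1,H06
T0271,2015,61.2,H12
T0272,2015,68.4,H06
T0273,2015,59.9,H06
T0274,2015,72.5,H02
T0275,2015,53.3,H05
T0276,2015,39.3,H03
T0277,2015,68.5,H06
T0278,2015,68.2,H10
T0279,2016,74.7,H10
T0067,2016,74.1,H10
T0035,2015,71.6,H04
T0087,2016,46.6,H04
T0071,2016,74.9,H03
T0048,2015,68.0,H04
T0016,2015,62.7,H10
T0086,2016,49.2,H05
T0073,2015,74.9,H10
T0095,2015,56.8,H12
T0108,2016,69.2,H03
T0043,2015,50.0,H02
T0090,2016,45.4,H04
T0085,2016,68.1,H07
T0107,2016,62.3,H10
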