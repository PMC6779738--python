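# Atlantic green turtle rookery demography: adult female abundance N,
# minimum distance to Lac Bay, Bonaire (D, km), weighted mean annual growth
# rate r, reproductive output proxy Nr, and temporal recruitment change dC
# (<75 cm and <50 cm SCL size classes). Regional rows carry region "-".
unit,region,N,D_km,r,Nr,dC_lt75,dC_lt50
North-western Caribbean,-,29003,1629,0.136,3944,0.26,0.41
South-western Caribbean,-,131751,1696,0.017,2240,0.00,0.02
Eastern Caribbean,-,22013,1009,0.066,1448,-0.22,-0.39
Southern Atlantic,-,46020,5985,0.035,1610,-0.04,-0.03
Mexico,NW,18257,2142,0.139,2538,0.09,0.03
Central Eastern Florida,NW,4990,1434,0.183,913,0.07,0.07
Southern Florida,NW,3314,1483,0.100,333,0.14,0.44
Cuba,NW,2226,1707,0.122,270,0.00,0.00
Cayman Islands,NW,72,1377,0.056,4,-0.06,-0.07
Costa Rica,SW,131751,1696,0.017,2240,0.02,-0.04
Buck Island,EA,63,475,0.056,4,-0.01,-0.02
Aves Island,EA,2833,538,0.045,127,-0.03,-0.07
Guadeloupe,EA,50,767,0.056,3,-0.02,-0.06
Suriname,EA,13067,1508,0.082,1065,-0.03,-0.23
French Guiana,EA,6000,1756,0.041,248,-0.18,-0.03
Rocas Atoll,SA,275,3965,0.024,7,0.00,0.00
Fernando de Noronha,SA,70,4115,0.035,2,0.00,0.00
Trindade Island,SA,2016,4825,0.035,71,0.00,0.00
Ascension Island,SA,13417,6161,0.043,577,-0.01,-0.01
Guinea Bissau,SA,29016,5849,0.035,1015,0.00,0.00
Sao Tome and Principe,SA,376,8382,0.035,13,0.00,-0.01
Bioko Island,SA,850,8596,-0.088,-75,0.03,0.01
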