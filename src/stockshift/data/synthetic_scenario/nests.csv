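# synthetic data, stockshift generator v0.1.0, seed 20160101
# nest-count series with known exponential growth plus lognormal noise
rookery,year,nests
R5,1996,390.0
R5,1997,314.0
R5,1998,461.0
R5,1999,495.0
R5,2000,465.0
R5,2001,665.0
R5,2002,543.0
R5,2003,482.0
R5,2004,725.0
R5,2005,982.0
R5,2006,779.0
R5,2007,760.0
R5,2008,1552.0
R5,2009,1492.0
R5,2010,1271.0
R5,2011,951.0
R5,2012,1602.0
R5,2013,1375.0
R5,2014,2000.0
R5,2015,2682.0
R6,1996,627.0
R6,1997,479.0
R6,1998,745.0
R6,1999,481.0
R6,2000,485.0
R6,2001,795.0
R6,2002,631.0
R6,2003,696.0
R6,2004,661.0
R6,2005,1118.0
R6,2006,1239.0
R6,2007,984.0
R6,2008,1294.0
R6,2009,1231.0
R6,2010,1171.0
R6,2011,1283.0
R6,2012,993.0
R6,2013,1251.0
R6,2014,942.0
R6,2015,942.0
R7,1996,788.0
R7,1997,713.0
R7,1998,873.0
R7,1999,1004.0
R7,2000,831.0
R7,2001,859.0
R7,2002,871.0
R7,2003,1335.0
R7,2004,1361.0
R7,2005,1173.0
R7,2006,1220.0
R7,2007,1575.0
R7,2008,1453.0
R7,2009,1150.0
R7,2010,1796.0
R7,2011,1516.0
R7,2012,1704.0
R7,2013,2195.0
R7,2014,2263.0
R7,2015,2204.0
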