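year,fur_seal_sets,sperm_whale_sets,orca_sets,no_mammal_sets,fur_seal_n,sperm_whale_n,orca_n,fur_seal_pct,sperm_whale_pct,orca_pct,fur_seal_ratio,sperm_whale_ratio,orca_ratio
1997,159,371,84,662,1493,765,669,11.24,26.24,5.94,1.06,0.54,0.47
1998,71,470,102,806,2168,1067,1008,4.73,31.31,6.80,1.44,0.71,0.67
1999,197,761,123,728,3822,1938,1347,10.34,39.93,6.45,2.01,1.02,0.71
2000,105,592,107,1124,3834,1384,778,5.14,28.99,5.24,1.88,0.68,0.38
2001,94,409,54,1085,237,615,85,4.66,20.28,2.68,0.12,0.30,0.04
2002,268,678,132,1842,2242,1295,1028,8.86,22.41,4.36,0.74,0.43,0.34
2003,300,1297,161,2637,5832,2466,1481,6.37,27.53,3.42,1.24,0.52,0.31
2004,245,652,89,1794,1467,1285,1076,8.06,21.46,2.93,0.48,0.42,0.35
2005,338,574,110,1018,1317,1338,645,15.64,26.56,5.09,0.61,0.62,0.30
2006,526,668,119,1218,2891,2378,971,20.45,25.97,4.63,1.12,0.92,0.38
2007,253,452,95,1425,1475,1087,903,11.34,20.25,4.26,0.66,0.49,0.40
2008,136,549,121,2065,979,1164,967,4.65,18.79,4.14,0.34,0.40,0.33
2009,620,634,107,1530,2879,1665,822,20.69,21.16,3.57,0.96,0.56,0.27
2010,65,512,138,1453,301,1394,842,2.96,23.35,6.29,0.14,0.64,0.38
2011,90,283,69,959,134,671,372,6.28,19.74,4.81,0.09,0.47,0.26
2012,17,518,77,912,35,1558,568,1.11,33.72,5.01,0.02,1.01,0.37
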