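locality_id,latitude,longitude,n,n_excl_fullsib,he,ho,fis
1,51.144111,5.156194,14,9,0.2023,0.2116,-0.05
2,51.148889,5.145,12,11,0.2439,0.232,0.032
3,51.145611,5.1405,17,17,0.2413,0.2222,0.071
4,51.137889,5.140889,14,11,0.213,0.2276,-0.053
5,51.186694,5.158389,14,12,0.2107,0.2121,-0.011
6,51.114389,5.136306,1,,,,
7,51.123389,5.1185,14,10,0.1849,0.1747,0.045
8,51.133194,5.11,16,14,0.2119,0.201,0.043
9,51.137111,5.103306,16,9,0.2215,0.2011,0.073
10,51.1365,5.096,2,2,0.237,0.2233,-0.065
11,51.136389,5.084889,1,,,,
12,51.147,5.064611,5,4,0.1992,0.2466,-0.226
13,51.154,5.070194,15,13,0.2255,0.2124,0.045
14,51.150306,5.039389,3,3,0.191,0.2405,-0.267
15,51.148806,5.029611,17,15,0.2397,0.2285,0.037
16,51.150111,5.015889,15,11,0.2395,0.2407,-0.008
17,51.144111,5.015806,13,13,0.2361,0.2264,0.031
18,51.141111,5.000611,17,7,0.2103,0.2305,-0.085
19,51.099611,4.981694,19,14,0.2319,0.2364,-0.015
20,51.095389,4.974806,13,10,0.234,0.2587,-0.091
21,51.095694,4.956611,18,14,0.2192,0.2157,0.016
22,51.076194,4.9885,1,,,,
23,51.0745,4.978389,19,8,0.186,0.1812,0.015
24,51.076306,4.967,16,14,0.2139,0.2235,-0.032
25,51.090889,4.932889,12,10,0.2355,0.2015,0.119
26,51.080611,4.884194,15,8,0.2191,0.22,-0.017
27,51.070194,4.856,19,12,0.2182,0.1983,0.072
28,51.0575,4.822611,11,9,0.1815,0.1743,0.029
29,51.0625,4.801611,5,3,0.1803,0.2347,-0.3
30,51.066694,4.769611,15,10,0.2008,0.1903,0.038
31,51.137806,4.607,3,2,0.1991,0.1836,-0.047
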