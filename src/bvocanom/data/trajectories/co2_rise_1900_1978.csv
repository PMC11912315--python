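year,delta_t_c,co2_ratio
1900,0.0,1.0
1901,0.0064,1.0113
1902,0.0128,1.0227
1903,0.0192,1.0343
1904,0.0256,1.0461
1905,0.0321,1.0581
1906,0.0385,1.0702
1907,0.0449,1.0826
1908,0.0513,1.0951
1909,0.0577,1.1078
1910,0.0641,1.1208
1911,0.0705,1.1339
1912,0.0769,1.1472
1913,0.0833,1.1607
1914,0.0897,1.1745
1915,0.0962,1.1885
1916,0.1026,1.2026
1917,0.109,1.2171
1918,0.1154,1.2317
1919,0.1218,1.2466
1920,0.1282,1.2617
1921,0.1346,1.2771
1922,0.141,1.2927
1923,0.1474,1.3086
1924,0.1538,1.3247
1925,0.1603,1.3411
1926,0.1667,1.3578
1927,0.1731,1.3747
1928,0.1795,1.3919
1929,0.1859,1.4094
1930,0.1923,1.4273
1931,0.1987,1.4454
1932,0.2051,1.4638
1933,0.2115,1.4825
1934,0.2179,1.5016
1935,0.2244,1.5209
1936,0.2308,1.5407
1937,0.2372,1.5607
1938,0.2436,1.5811
1939,0.25,1.6019
1940,0.2564,1.623
1941,0.2628,1.6445
1942,0.2692,1.6663
1943,0.2756,1.6886
1944,0.2821,1.7113
1945,0.2885,1.7343
1946,0.2949,1.7578
1947,0.3013,1.7817
1948,0.3077,1.8061
1949,0.3141,1.8308
1950,0.3205,1.8561
1951,0.3269,1.8818
1952,0.3333,1.908
1953,0.3397,1.9346
1954,0.3462,1.9618
1955,0.3526,1.9895
1956,0.359,2.0177
1957,0.3654,2.0464
1958,0.3718,2.0757
1959,0.3782,2.1055
1960,0.3846,2.1359
1961,0.391,2.1669
1962,0.3974,2.1985
1963,0.4038,2.2307
1964,0.4103,2.2636
1965,0.4167,2.2971
1966,0.4231,2.3312
1967,0.4295,2.366
1968,0.4359,2.4016
1969,0.4423,2.4378
1970,0.4487,2.4748
1971,0.4551,2.5125
1972,0.4615,2.551
1973,0.4679,2.5902
1974,0.4744,2.6303
1975,0.4808,2.6712
1976,0.4872,2.713
1977,0.4936,2.7556
1978,0.5,2.7992
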