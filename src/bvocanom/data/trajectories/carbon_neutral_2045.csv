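year,delta_t_c,co2_ratio
2025,1.91,0.616
2026,1.94,0.612
2027,1.97,0.608
2028,2.0,0.604
2029,2.03,0.6
2030,2.06,0.596
2031,2.09,0.592
2032,2.12,0.588
2033,2.15,0.584
2034,2.18,0.58
2035,2.21,0.576
2036,2.24,0.572
2037,2.27,0.568
2038,2.3,0.564
2039,2.33,0.56
2040,2.36,0.556
2041,2.39,0.552
2042,2.42,0.548
2043,2.45,0.544
2044,2.48,0.54
2045,2.51,0.536
2046,2.54,0.536
2047,2.57,0.536
2048,2.6,0.536
2049,2.63,0.536
2050,2.66,0.536
2051,2.69,0.536
2052,2.72,0.536
2053,2.75,0.536
2054,2.78,0.536
2055,2.81,0.536
2056,2.84,0.536
2057,2.87,0.536
2058,2.9,0.536
2059,2.93,0.536
2060,2.96,0.536
2061,2.99,0.536
2062,3.02,0.536
2063,3.05,0.536
2064,3.08,0.536
2065,3.11,0.536
2066,3.14,0.536
2067,3.17,0.536
2068,3.2,0.536
2069,3.23,0.536
2070,3.26,0.536
2071,3.29,0.536
2072,3.32,0.536
2073,3.35,0.536
2074,3.38,0.536
2075,3.41,0.536
2076,3.44,0.536
2077,3.47,0.536
2078,3.5,0.536
2079,3.53,0.536
2080,3.56,0.536
2081,3.59,0.536
2082,3.62,0.536
2083,3.65,0.536
2084,3.68,0.536
2085,3.71,0.536
2086,3.74,0.536
2087,3.77,0.536
2088,3.8,0.536
2089,3.83,0.536
2090,3.86,0.536
2091,3.89,0.536
2092,3.92,0.536
2093,3.95,0.536
2094,3.98,0.536
2095,4.01,0.536
2096,4.04,0.536
2097,4.07,0.536
2098,4.1,0.536
2099,4.13,0.536
2100,4.16,0.536
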