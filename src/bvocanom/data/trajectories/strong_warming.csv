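year,delta_t_c,co2_ratio
2025,2.1189,0.62
2026,2.1639,0.6183
2027,2.209,0.6167
2028,2.2541,0.615
2029,2.2992,0.6134
2030,2.3443,0.6117
2031,2.3893,0.6101
2032,2.4344,0.6084
2033,2.4795,0.6068
2034,2.5246,0.6051
2035,2.5697,0.6035
2036,2.6148,0.6018
2037,2.6598,0.6002
2038,2.7049,0.5985
2039,2.75,0.5969
2040,2.7951,0.5952
2041,2.8402,0.5935
2042,2.8852,0.5919
2043,2.9303,0.5902
2044,2.9754,0.5886
2045,3.0205,0.5869
2046,3.0656,0.5853
2047,3.1107,0.5836
2048,3.1557,0.582
2049,3.2008,0.5803
2050,3.2459,0.5787
2051,3.291,0.577
2052,3.3361,0.5754
2053,3.3811,0.5737
2054,3.4262,0.5721
2055,3.4713,0.5704
2056,3.5164,0.5687
2057,3.5615,0.5671
2058,3.6066,0.5654
2059,3.6516,0.5638
2060,3.6967,0.5621
2061,3.7418,0.5605
2062,3.7869,0.5588
2063,3.832,0.5572
2064,3.877,0.5555
2065,3.9221,0.5539
2066,3.9672,0.5522
2067,4.0123,0.5506
2068,4.0574,0.5489
2069,4.1025,0.5473
2070,4.1475,0.5456
2071,4.1926,0.5439
2072,4.2377,0.5423
2073,4.2828,0.5406
2074,4.3279,0.539
2075,4.373,0.5373
2076,4.418,0.5357
2077,4.4631,0.534
2078,4.5082,0.5324
2079,4.5533,0.5307
2080,4.5984,0.5291
2081,4.6434,0.5274
2082,4.6885,0.5258
2083,4.7336,0.5241
2084,4.7787,0.5225
2085,4.8238,0.5208
2086,4.8689,0.5191
2087,4.9139,0.5175
2088,4.959,0.5158
2089,5.0041,0.5142
2090,5.0492,0.5125
2091,5.0943,0.5109
2092,5.1393,0.5092
2093,5.1844,0.5076
2094,5.2295,0.5059
2095,5.2746,0.5043
2096,5.3197,0.5026
2097,5.3648,0.501
2098,5.4098,0.4993
2099,5.4549,0.4977
2100,5.5,0.496
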