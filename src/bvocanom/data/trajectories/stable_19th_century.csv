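year,delta_t_c,co2_ratio
1800,0.0,1.0
1801,0.0,1.0
1802,0.0,1.0
1803,0.0,1.0
1804,0.0,1.0
1805,0.0,1.0
1806,0.0,1.0
1807,0.0,1.0
1808,0.0,1.0
1809,0.0,1.0
1810,0.0,1.0
1811,0.0,1.0
1812,0.0,1.0
1813,0.0,1.0
1814,0.0,1.0
1815,0.0,1.0
1816,0.0,1.0
1817,0.0,1.0
1818,0.0,1.0
1819,0.0,1.0
1820,0.0,1.0
1821,0.0,1.0
1822,0.0,1.0
1823,0.0,1.0
1824,0.0,1.0
1825,0.0,1.0
1826,0.0,1.0
1827,0.0,1.0
1828,0.0,1.0
1829,0.0,1.0
1830,0.0,1.0
1831,0.0,1.0
1832,0.0,1.0
1833,0.0,1.0
1834,0.0,1.0
1835,0.0,1.0
1836,0.0,1.0
1837,0.0,1.0
1838,0.0,1.0
1839,0.0,1.0
1840,0.0,1.0
1841,0.0,1.0
1842,0.0,1.0
1843,0.0,1.0
1844,0.0,1.0
1845,0.0,1.0
1846,0.0,1.0
1847,0.0,1.0
1848,0.0,1.0
1849,0.0,1.0
1850,0.0,1.0
1851,0.0,1.0
1852,0.0,1.0
1853,0.0,1.0
1854,0.0,1.0
1855,0.0,1.0
1856,0.0,1.0
1857,0.0,1.0
1858,0.0,1.0
1859,0.0,1.0
1860,0.0,1.0
1861,0.0,1.0
1862,0.0,1.0
1863,0.0,1.0
1864,0.0,1.0
1865,0.0,1.0
1866,0.0,1.0
1867,0.0,1.0
1868,0.0,1.0
1869,0.0,1.0
1870,0.0,1.0
1871,0.0,1.0
1872,0.0,1.0
1873,0.0,1.0
1874,0.0,1.0
1875,0.0,1.0
1876,0.0,1.0
1877,0.0,1.0
1878,0.0,1.0
1879,0.0,1.0
1880,0.0,1.0
1881,0.0,1.0
1882,0.0,1.0
1883,0.0,1.0
1884,0.0,1.0
1885,0.0,1.0
1886,0.0,1.0
1887,0.0,1.0
1888,0.0,1.0
1889,0.0,1.0
1890,0.0,1.0
1891,0.0,1.0
1892,0.0,1.0
1893,0.0,1.0
1894,0.0,1.0
1895,0.0,1.0
1896,0.0,1.0
1897,0.0,1.0
1898,0.0,1.0
1899,0.0,1.0
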