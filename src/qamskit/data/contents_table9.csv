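batch,n,l1_es_mean,l1_es_sd,l3_qams_mean,l3_qams_sd,l3_es_mean,l3_es_sd,l4_qams_mean,l4_qams_sd,l4_es_mean,l4_es_sd
20200405,3,0.2021,0.0079,0.2901,0.0056,0.2899,0.0109,0.1675,0.0083,0.1676,0.0107
20200419,3,0.3232,0.0102,0.2684,0.0067,0.2687,0.0070,0.1743,0.0068,0.1743,0.0078
20200602,3,0.2682,0.0072,0.2767,0.0085,0.2768,0.0089,0.1834,0.0087,0.1835,0.0093
20200617,3,0.1355,0.0087,0.1897,0.0086,0.1899,0.0088,0.1737,0.0102,0.1738,0.0098
20200912,3,0.2682,0.0110,0.3322,0.0104,0.3320,0.0097,0.2011,0.0096,0.2009,0.0106
20200926,3,0.3127,0.0067,0.2798,0.0113,0.2797,0.0109,0.1932,0.0078,0.1930,0.0093
20201218,3,0.2356,0.0093,0.2669,0.0098,0.2667,0.0111,0.1736,0.0069,0.1735,0.0076
10101222,3,0.3823,0.0095,0.2638,0.0087,0.2637,0.0094,0.1865,0.0109,0.1866,0.0099
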