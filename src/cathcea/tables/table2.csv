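anatomy,treatment,age_band,n,year,mean,ci_low,ci_high
left_main,medical,lt65,98,1,2166,710,3622
left_main,medical,lt65,98,2,1793,488,3100
left_main,medical,lt65,98,3,1641,380,2903
left_main,medical,65_75,117,1,4312,2941,5683
left_main,medical,65_75,117,2,3806,2265,5347
left_main,medical,65_75,117,3,3527,1765,5290
left_main,medical,gt75,70,1,3756,2112,5401
left_main,medical,gt75,70,2,5777,2835,8719
left_main,medical,gt75,70,3,2703,938,4468
left_main,pci,lt65,43,1,5913,3749,8077
left_main,pci,lt65,43,2,3580,1014,6146
left_main,pci,lt65,43,3,1332,256,2407
left_main,pci,65_75,35,1,4597,2428,6765
left_main,pci,65_75,35,2,5536,893,10179
left_main,pci,65_75,35,3,1680,543,2817
left_main,pci,gt75,11,1,4123,946,7300
left_main,pci,gt75,11,2,7739,0,16190
left_main,pci,gt75,11,3,3180,0,8731
left_main,cabg,lt65,330,1,10990,9581,12399
left_main,cabg,lt65,330,2,1414,1045,1782
left_main,cabg,lt65,330,3,1392,1000,1784
left_main,cabg,65_75,382,1,15342,13486,17198
left_main,cabg,65_75,382,2,2041,1656,2426
left_main,cabg,65_75,382,3,2413,1708,3117
left_main,cabg,gt75,150,1,11884,9387,14381
left_main,cabg,gt75,150,2,2385,1626,3143
left_main,cabg,gt75,150,3,1909,1375,2444
three_vessel,medical,lt65,684,1,2467,2038,2896
three_vessel,medical,lt65,684,2,3348,2568,4127
three_vessel,medical,lt65,684,3,2790,2188,3392
three_vessel,medical,65_75,631,1,3880,3289,4470
three_vessel,medical,65_75,631,2,4552,3782,5322
three_vessel,medical,65_75,631,3,3495,2811,4179
three_vessel,medical,gt75,352,1,4121,3329,4913
three_vessel,medical,gt75,352,2,3394,2580,4208
three_vessel,medical,gt75,352,3,3235,2375,4095
three_vessel,pci,lt65,646,1,5139,4530,5748
three_vessel,pci,lt65,646,2,2503,1991,3014
three_vessel,pci,lt65,646,3,2150,1700,2601
three_vessel,pci,65_75,387,1,6617,5612,7621
three_vessel,pci,65_75,387,2,3217,2565,3869
three_vessel,pci,65_75,387,3,3494,2759,4229
three_vessel,pci,gt75,186,1,5545,4504,6585
three_vessel,pci,gt75,186,2,3706,2457,4955
three_vessel,pci,gt75,186,3,2568,1901,3234
three_vessel,cabg,lt65,881,1,13539,12463,14615
three_vessel,cabg,lt65,881,2,1586,1334,1839
three_vessel,cabg,lt65,881,3,1412,1166,1658
three_vessel,cabg,65_75,697,1,17444,16006,18882
three_vessel,cabg,65_75,697,2,2503,2124,2882
three_vessel,cabg,65_75,697,3,2319,1959,2680
three_vessel,cabg,gt75,256,1,18291,15613,20969
three_vessel,cabg,gt75,256,2,2943,2163,3722
three_vessel,cabg,gt75,256,3,2458,1876,3040
one_two_vessel,medical,lt65,4132,1,2616,2375,2857
one_two_vessel,medical,lt65,4132,2,1808,1635,1980
one_two_vessel,medical,lt65,4132,3,1658,1494,1821
one_two_vessel,medical,65_75,1773,1,3866,3398,4334
one_two_vessel,medical,65_75,1773,2,2988,2644,3333
one_two_vessel,medical,65_75,1773,3,2883,2570,3197
one_two_vessel,medical,gt75,670,1,4420,3758,5081
one_two_vessel,medical,gt75,670,2,3624,2965,4283
one_two_vessel,medical,gt75,670,3,3144,2513,3774
one_two_vessel,pci,lt65,2495,1,4351,4046,4657
one_two_vessel,pci,lt65,2495,2,1739,1553,1925
one_two_vessel,pci,lt65,2495,3,1487,1328,1647
one_two_vessel,pci,65_75,1063,1,5095,4617,5574
one_two_vessel,pci,65_75,1063,2,2691,2350,3031
one_two_vessel,pci,65_75,1063,3,2708,2321,3096
one_two_vessel,pci,gt75,388,1,5792,4955,6630
one_two_vessel,pci,gt75,388,2,2797,2241,3353
one_two_vessel,pci,gt75,388,3,2903,2236,3570
one_two_vessel,cabg,lt65,490,1,13937,12369,15505
one_two_vessel,cabg,lt65,490,2,1865,1468,2260
one_two_vessel,cabg,lt65,490,3,1660,1198,2123
one_two_vessel,cabg,65_75,301,1,17732,15482,19982
one_two_vessel,cabg,65_75,301,2,2400,1832,2969
one_two_vessel,cabg,65_75,301,3,2110,1656,2564
one_two_vessel,cabg,gt75,111,1,16910,13050,20771
one_two_vessel,cabg,gt75,111,2,3138,1670,4605
one_two_vessel,cabg,gt75,111,3,2928,1375,4481
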