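scenario,anatomy,window_start,window_end,rr,ci_low,ci_high,source
yusuf,left_main,0,5,2.33,1.27,4.60,estimated
yusuf,left_main,5,10,0.74,0.46,1.21,estimated
yusuf,left_main,10,inf,1.00,,,assumed
yusuf,three_vessel,0,5,1.59,1.21,2.14,estimated
yusuf,three_vessel,5,10,1.00,0.87,1.14,estimated
yusuf,three_vessel,10,inf,1.00,,,assumed
yusuf,one_two_vessel,0,5,1.27,0.88,1.85,estimated
yusuf,one_two_vessel,5,10,0.80,0.70,0.91,estimated
yusuf,one_two_vessel,10,inf,1.00,,,assumed
frisc2,all,0,2,1.47,,,estimated
frisc2,all,2,5,0.88,,,estimated
frisc2,all,5,inf,1.00,,,assumed
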