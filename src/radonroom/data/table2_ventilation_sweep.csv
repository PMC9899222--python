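ach_per_h,numerical_open_bq_m3,numerical_closed_bq_m3,analytical_bq_m3,diff_open_pct,diff_closed_pct
0.3,195.65,213.70,221.60,11.71,3.56
0.5,124.07,130.37,138.22,10.23,5.68
1.0,66.25,70.21,74.59,11.17,5.87
1.5,47.07,50.33,53.17,11.46,5.34
2.0,37.76,40.10,42.42,10.97,5.47
4.3,20.17,23.32,25.11,19.67,7.11
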