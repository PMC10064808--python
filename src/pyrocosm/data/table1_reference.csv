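fire_temp,depth_cm,t_statistic,p_value,p_is_upper_bound,mean_bare_C,mean_bsc_C,max_bare_C,max_bsc_C
450,2,6.44,0.001,True,123.14,94.80,304.4,301.7
450,5,12.69,0.001,True,53.91,36.88,106.2,68.93
450,8,11.89,0.001,True,30.28,23.30,48.52,32.37
600,2,12.85,0.001,True,190.95,94.07,502.1,479.3
600,5,13.17,0.001,True,46.76,31.36,85.1,51.95
600,8,14.12,0.001,True,38.37,23.55,75.86,29.89
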