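roi,duration_s,contrast,side,amplitude_pct,se_pct,n_runs
V2,6.0,0.05,single_A,0.41541476263855426,0.06708203932499368,5.0
V2,6.0,0.05,single_B,0.42217598689336794,0.06708203932499368,5.0
V2,6.0,0.05,double,0.5566068181348799,0.06708203932499368,5.0
V2,6.0,0.1057371263440564,single_A,0.8341951623107928,0.06708203932499368,5.0
V2,6.0,0.1057371263440564,single_B,0.7430594236481985,0.06708203932499368,5.0
V2,6.0,0.1057371263440564,double,1.1384591932618877,0.06708203932499368,5.0
V2,6.0,0.22360679774997896,single_A,1.3554997262723034,0.06708203932499368,5.0
V2,6.0,0.22360679774997896,single_B,1.372315920851499,0.06708203932499368,5.0
V2,6.0,0.22360679774997896,double,1.8362152411388286,0.06708203932499368,5.0
V2,6.0,0.47287080450158786,single_A,1.680688005470563,0.06708203932499368,5.0
V2,6.0,0.47287080450158786,single_B,1.7925627099454582,0.06708203932499368,5.0
V2,6.0,0.47287080450158786,double,2.4895517899522344,0.06708203932499368,5.0
V2,6.0,1.0,single_A,2.0010181181419435,0.06708203932499368,5.0
V2,6.0,1.0,single_B,1.9600160079980684,0.06708203932499368,5.0
V2,6.0,1.0,double,2.7116358155876044,0.06708203932499368,5.0
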