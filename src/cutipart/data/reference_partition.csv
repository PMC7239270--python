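hour,k,k_se,t_ad,t_ad_se,t_ab,t_ab_se,t_ab_c,t_ab_c_se,t_ad_intra,t_ad_intra_se,t_ab_intra,t_ab_intra_se,t_ab_intra_c,t_ab_intra_c_se
1,0.206,0.019,0.094,0.011,0.199,0.006,0.142,0.002,0.104,0.002,0.452,0.008,0.413,0.004
2,0.211,0.022,0.095,0.012,0.190,0.005,0.133,0.003,0.097,0.005,0.437,0.009,0.398,0.003
3,0.224,0.035,0.069,0.003,0.198,0.017,0.141,0.013,0.077,0.010,0.422,0.022,0.383,0.017
4,0.213,0.036,0.061,0.007,0.189,0.023,0.132,0.019,0.087,0.005,0.417,0.012,0.378,0.006
5,0.238,0.031,0.053,0.010,0.154,0.017,0.096,0.013,0.078,0.013,0.426,0.006,0.387,0.004
6,0.293,0.034,0.029,0.014,0.172,0.005,0.115,0.008,0.048,0.006,0.405,0.012,0.365,0.006
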