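# Default synthetic-experiment parameters (see cutipart.synthetic_leaf).
# Rates in mg h-1 cm-2, weights in g, areas in cm2, times in hours.
g_ad_full: 0.094
g_ad_intra: 0.104
g_ab_full: 0.142
g_ab_intra: 0.413
g_s0: 0.057
t_c: 4.5
r: 3.0
beta: 0.2
k_ad: 0.206
k_ab: 0.206
aba_factor: 0.66
area_mean: 35.0
area_sd: 4.0
water_content_mean: 0.90
water_content_sd: 0.08
w_dry_mean: 0.45
noise_sd: 0.001
n_leaves: 6
horizon: 10.0
dt: 0.01
seed: 0
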