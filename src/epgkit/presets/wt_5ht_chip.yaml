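# Wild-type N2 in 10 mM serotonin, on-chip recording
name: wt_5ht_chip
freq_mean: 3.467
dur_mean: 0.101
p_rate: 0.126
amp_pp_mean: 8.370
e_amp_mean: 1.753
re_ratio_mean: 1.143
freq_cv: 0.3
dur_cv: 0.08
amp_pp_cv: 0.10
e_amp_cv: 0.10
re_ratio_cv: 0.05
worm_cv: 0.05
p_amp_frac: 0.35
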