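# Wild-type N2, basal pumping, on-chip recording
name: wt_basal_chip
freq_mean: 0.075
dur_mean: 0.116
p_rate: 1.788
amp_pp_mean: 4.410
e_amp_mean: 0.257
re_ratio_mean: 1.222
freq_cv: 0.3
dur_cv: 0.08
amp_pp_cv: 0.10
e_amp_cv: 0.10
re_ratio_cv: 0.05
worm_cv: 0.05
p_amp_frac: 0.35
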