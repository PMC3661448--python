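# Wild-type N2, basal pumping, conventional suction-electrode recording
name: wt_basal_conventional
freq_mean: 0.060
dur_mean: 0.112
p_rate: 0.590
amp_pp_mean: 4.780
e_amp_mean: 0.203
re_ratio_mean: 1.006
freq_cv: 0.3
dur_cv: 0.08
amp_pp_cv: 0.10
e_amp_cv: 0.10
re_ratio_cv: 0.05
worm_cv: 0.05
p_amp_frac: 0.35
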