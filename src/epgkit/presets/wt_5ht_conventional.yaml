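# Wild-type N2 in 10 mM serotonin, conventional recording
name: wt_5ht_conventional
freq_mean: 1.878
dur_mean: 0.135
p_rate: 0.201
amp_pp_mean: 7.580
e_amp_mean: 1.080
re_ratio_mean: 1.046
freq_cv: 0.3
dur_cv: 0.08
amp_pp_cv: 0.10
e_amp_cv: 0.10
re_ratio_cv: 0.05
worm_cv: 0.05
p_amp_frac: 0.35
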