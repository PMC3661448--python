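# eat-4 mutant, conventional recording (amplitude unreported; wild-type value)
name: eat4_conventional
freq_mean: 0.055
dur_mean: 0.287
p_rate: 0.280
amp_pp_mean: 4.780
e_amp_mean: 0.368
re_ratio_mean: 2.170
freq_cv: 0.3
dur_cv: 0.08
amp_pp_cv: 0.10
e_amp_cv: 0.10
re_ratio_cv: 0.05
worm_cv: 0.05
p_amp_frac: 0.35
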