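# Worm recorded tail-first: small monophasic blips, no EPG fine structure
kind: tail
name: tail
blip_rate: 0.7
amp_mean: 0.70
blip_width: 0.012
rate_cv: 0.3
amp_cv: 0.10
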