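diversity_knob	mean_lzc	sd_lzc	n_participants	duration_s
0.0000	0.9781	0.0044	8	60.0000
0.3000	0.9091	0.0250	8	60.0000
0.6000	0.7153	0.0396	8	60.0000
0.9000	0.3803	0.0267	8	60.0000
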