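block	quantity	log_or	se	p	ci_low	ci_high
AHRR-cg05575921	TCE	1.83	0.29	0.001	1.37	2.64
AHRR-cg05575921	NDE	1.26	0.31	0.001	0.75	2.08
AHRR-cg05575921	NIE	0.56	0.08	0.001	0.39	0.73
AHRR-cg05575921	Effect mediated	0.31	0.08	0.001	0.18	0.46
F2RL3-cg03636183	TCE	1.82	0.30	0.001	1.29	2.48
F2RL3-cg03636183	NDE	1.23	0.33	0.001	0.63	1.93
F2RL3-cg03636183	NIE	0.59	0.09	0.001	0.43	0.80
F2RL3-cg03636183	Effect mediated	0.32	0.08	0.001	0.20	0.53
joint	TCE	1.79	0.30	0.001	1.28	2.53
joint	NDE	1.13	0.34	0.001	0.49	1.86
joint	NIE	0.66	0.15	0.001	0.42	1.09
joint	Effect mediated	0.37	0.11	0.001	0.19	0.66
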