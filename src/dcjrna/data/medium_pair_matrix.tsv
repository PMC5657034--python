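	G1	G2	G3	G4	G5	G6
F1	0.39	0.43	0.16	0.2	0.71	0.35
F2	0.11	0.23	0.13	0.16	0.23	0.12
F3	0.56	0.95	0.44	0.53	0.68	0.59
F4	0.52	0.51	0.96	0.92	0.29	0.58
F5	0.81	0.66	0.63	0.72	0.48	0.9
F6	0.54	0.65	0.28	0.33	0.99	0.55
F7	0.91	0.62	0.55	0.64	0.55	1.0
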