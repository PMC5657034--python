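	b1	b2	b3	b4
a1	0.39	0.24	0.29	0.29
a2	0.34	0.83	0.75	0.75
a3	0.25	0.86	1	1
a4	0.22	0.66	0.56	0.56
a5	0.25	0.86	1	1
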