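	E1	E2	E3	E4
D1	0.97	0.65	0.39	0.22
D2	0.5	0.74	0.35	0.21
D3	0.21	0.29	0.61	0.95
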