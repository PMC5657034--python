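A = (85, INTERM = {}, INTRAM = {a_1 = (1, 75, 7), a_2 = (10, 24, 3), a_3 = (28, 40, 5), a_4 = (46, 53, 3), a_5 = (58, 70, 5)})
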