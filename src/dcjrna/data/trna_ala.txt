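B = (76, INTERM = {}, INTRAM = {b_1 = (1, 66, 7), b_2 = (10, 22, 4), b_3 = (27, 39, 5), b_4 = (49, 61, 5)})
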