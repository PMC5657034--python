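	I1	I2	I3	I4	I5	I6	I7	I8	I9	I10	I11	I12
H1	0.35	0.63	0.83	0.13	0.11	0.2	0.15	0.23	0.38	0.39	0.67	0.62
H2	0.44	0.59	1.0	0.13	0.15	0.2	0.14	0.21	0.41	0.38	0.65	0.66
H3	0.26	0.24	0.13	1.0	0.37	0.7	0.77	0.26	0.04	0.44	0.24	0.07
H4	0.42	0.11	0.15	0.37	1.0	0.56	0.31	0.09	0.1	0.23	0.2	0.12
H5	0.41	0.21	0.2	0.7	0.56	1.0	0.64	0.21	0.06	0.45	0.37	0.11
H6	0.27	0.27	0.14	0.77	0.31	0.64	1.0	0.37	0.04	0.48	0.26	0.08
H7	0.27	0.41	0.21	0.26	0.09	0.21	0.37	1.0	0.06	0.52	0.36	0.11
H8	0.21	0.21	0.41	0.04	0.1	0.06	0.04	0.06	1.0	0.12	0.23	0.66
H9	0.6	0.57	0.38	0.44	0.23	0.45	0.48	0.52	0.12	1.0	0.63	0.21
H10	0.57	0.64	0.65	0.24	0.2	0.37	0.26	0.36	0.23	0.63	1.0	0.39
H11	0.36	0.36	0.66	0.07	0.12	0.11	0.08	0.11	0.66	0.21	0.39	1.0
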