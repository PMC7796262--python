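gene_a	gene_b	ka	ks	ratio
StbZIP55	StbZIP54	0.18	0.63	0.29
StbZIP38	StbZIP37	0.19	0.67	0.29
StbZIP38	StbZIP36	0.39	2.86	0.14
StbZIP29	StbZIP30	0.36	1.88	0.19
StbZIP23	StbZIP19	0.17	0.67	0.26
StbZIP27	StbZIP14	0.4	1.33	0.30
StbZIP14	StbZIP37	0.69	1.43	0.48
StbZIP11	StbZIP44	0.26	1.17	0.23
StbZIP6	StbZIP7	0.44	1.39	0.32
StbZIP6	StbZIP5	0.26	0.87	0.30
StbZIP5	StbZIP6	0.26	0.87	0.30
StbZIP7	StbZIP6	0.44	1.39	0.32
StbZIP36	StbZIP38	0.39	2.86	0.14
StbZIP44	StbZIP11	0.26	1.17	0.23
StbZIP30	StbZIP29	0.36	1.88	0.19
StbZIP54	StbZIP55	0.18	0.63	0.29
StbZIP61	StbZIP34	0.25	1.1	0.23
StbZIP37	StbZIP38	0.19	0.67	0.29
StbZIP19	StbZIP23	0.17	0.67	0.26
StbZIP66	StbZIP12	0.15	0.57	0.26
StbZIP12	StbZIP66	0.15	0.57	0.26
StbZIP34	StbZIP61	0.25	1.1	0.23
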