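gene_a	gene_b	chrom_a	chrom_b	ks	ka	ratio	selection	dup_type	t_mya
PvC3H29	PvC3H39	Chr5a	Chr5b	0.000	0.041	NA	diversifying	homeologous	NA
PvC3H34	PvC3H45	Chr5a	Chr5b	0.000	0.036	NA	diversifying	homeologous	NA
PvC3H62	PvC3H66	Chr9a	Chr9b	0.000	0.018	NA	diversifying	homeologous	NA
PvC3H54	PvC3H57	Chr7a	Chr7b	0.039	0.052	1.316	diversifying	homeologous	3
PvC3H33	PvC3H41	Chr5a	Chr5b	0.041	0.019	0.459	purifying	homeologous	3.1
PvC3H6	PvC3H7	Chr1a	Chr1b	0.046	0.075	1.649	diversifying	homeologous	3.5
PvC3H61	PvC3H65	Chr9a	Chr9b	0.047	0.030	0.638	purifying	homeologous	3.6
PvC3H32	PvC3H42	Chr5a	Chr5b	0.060	0.006	0.104	purifying	homeologous	4.6
PvC3H35	PvC3H44	Chr5a	Chr5b	0.065	0.044	0.672	purifying	homeologous	5
PvC3H1	PvC3H9	Chr1a	Chr1b	0.073	0.061	0.841	purifying	homeologous	5.6
PvC3H31	PvC3H43	Chr5a	Chr5b	0.076	0.066	0.874	purifying	homeologous	5.8
PvC3H10	PvC3H15	Chr2a	Chr2b	0.082	0.092	1.119	diversifying	homeologous	6.3
PvC3H30	PvC3H40	Chr5a	Chr5b	0.102	0.084	0.825	purifying	homeologous	7.9
PvC3H20	PvC3H23	Chr3a	Chr3b	0.131	0.064	0.489	purifying	homeologous	10.1
PvC3H46	PvC3H51	Chr6a	Chr6b	0.151	0.013	0.087	purifying	homeologous	11.6
PvC3H5	PvC3H6	Chr1a	Chr1a	0.163	0.060	0.367	purifying	tandem	12.5
PvC3H17	PvC3H50	Chr3a	Chr6b	0.237	0.030	0.128	purifying	paralogous	18.2
PvC3H32	PvC3H33	Chr5a	Chr5a	0.282	0.444	1.575	diversifying	tandem	21.7
PvC3H41	PvC3H42	Chr5b	Chr5b	0.287	0.464	1.616	diversifying	tandem	22.1
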