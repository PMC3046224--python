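network_id	richness	n_plants	n_bats	nodf	h2_prime	m	n_modules	r_bats	r_plants
Faria 1996	23	15	8	0.55	0.36	0.33	4	0.59	0.69
Garcia et al. 2000	20	14	6	0.41	0.39	0.44	5	0.41	0.58
Gorchov et al. 1995	37	26	11	0.67	0.30	0.24	4	0.69	0.84
Hayashi 1996	19	12	7	0.53	0.51	0.32	4	0.55	0.63
Kalko BCI	69	47	22	0.39	n/a	0.36	6	0.65	0.74
Lopez et al. 2006	50	36	14	0.48	0.34	0.36	4	0.65	0.78
Passos et al. 2003	29	22	7	0.58	0.39	0.33	4	0.50	0.68
Pedro 1992	18	11	7	0.64	0.48	0.29	4	0.42	0.60
Silveira 2006	12	6	6	0.75	0.18	0.20	3	0.53	0.59
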