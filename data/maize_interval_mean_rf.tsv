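background	interval	configuration	sex	mean_rf	se	n_plants
M	sh1-wx1	hybrid	male	16.6	1.0	8
M	sh1-wx1	hybrid	female	11.2	0.7	10
M	sh1-wx1	juxtaposed	male	38.3	1.0	6
M	sh1-wx1	juxtaposed	female	30.2	1.1	11
Ku	sh1-wx1	hybrid	male	16.8	0.9	6
Ku	sh1-wx1	hybrid	female	15.3	0.6	11
Ku	sh1-wx1	juxtaposed	male	37.2	1.7	7
Ku	sh1-wx1	juxtaposed	female	37.3	1.2	9
M	c1-sh1	hybrid	male	5.7	0.5	6
M	c1-sh1	hybrid	female	5.2	0.3	10
M	c1-sh1	juxtaposed	male	10.0	1.7	6
M	c1-sh1	juxtaposed	female	10.9	2.1	7
Ku	c1-sh1	hybrid	male	5.3	0.3	5
Ku	c1-sh1	hybrid	female	5.2	0.3	8
Ku	c1-sh1	juxtaposed	male	9.6	1.8	6
Ku	c1-sh1	juxtaposed	female	10.1	1.9	10
M	lg1-gl2	hybrid	male	20.0	2.3	5
M	lg1-gl2	hybrid	female	18.8	0.8	12
M	lg1-gl2	juxtaposed	male	28.1	1.4	8
M	lg1-gl2	juxtaposed	female	26.4	1.8	8
Ku	lg1-gl2	hybrid	male	17.3	1.1	3
Ku	lg1-gl2	hybrid	female	16.7	0.7	10
Ku	lg1-gl2	juxtaposed	male	34.5	1.4	8
Ku	lg1-gl2	juxtaposed	female	42.3	1.4	11
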