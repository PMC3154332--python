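locus	n_alleles	ho	he	null_freq	hwe_p
Agt5	2	0.053	0.235	0.626	0.012
Agt9	2	0.125	0.120	-0.032	1.000
Agt10	3	0.417	0.377	-0.061	0.483
Agt13	3	0.125	0.121	-0.025	1.000
Agt16	2	0.167	0.156	-0.044	1.000
Agt20	2	0.250	0.223	-0.067	1.000
Agt21	6	0.625	0.785	0.103	0.242
Agt23	2	0.042	0.042	-0.011	NA
Agt24	7	0.727	0.778	0.022	0.513
Agt25	2	0.042	0.042	-0.011	NA
Agt32	4	0.875	0.668	-0.145	0.182
Agt38	2	0.087	0.085	-0.022	1.000
Agt39	5	0.739	0.728	-0.019	0.791
Agt41	9	0.917	0.839	-0.055	0.595
Agt42	5	0.333	0.420	0.105	0.181
Agt44	2	0.208	0.191	-0.055	1.000
Agt45	3	0.522	0.581	0.043	0.394
Agt47	3	0.391	0.476	0.087	0.243
Agt48	6	0.875	0.757	-0.083	0.786
Agt49	5	0.417	0.621	0.186	0.012
Agt50	9	0.833	0.715	-0.087	0.364
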