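animal_id	role	diploid_n	rb_count	mean_ratio_pct
het_father	parent	32	8	21.51
A	descendant	37	3	21.11
B	descendant	35	5	25.61
C	descendant	37	3	21.7
D	descendant	38	2	26.28
E	descendant	36	4	25.22
F	descendant	35	5	22.29
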