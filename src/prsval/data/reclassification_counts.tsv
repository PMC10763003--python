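group	baseline_category	lt_1.66	1.66_to_lt_2.5	ge_2.5
cases	lt_1.66	503	94	23
cases	1.66_to_lt_2.5	72	134	74
cases	ge_2.5	2	8	12
controls	lt_1.66	1146	126	13
controls	1.66_to_lt_2.5	185	245	106
controls	ge_2.5	4	9	10
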