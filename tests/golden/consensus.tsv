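pos	A	C	G	T	info_bits
1	0.0000	1.0000	0.0000	0.0000	2.0000
2	0.0000	0.0000	0.0000	1.0000	2.0000
3	0.0000	1.0000	0.0000	0.0000	2.0000
4	0.0000	0.0000	1.0000	0.0000	2.0000
5	1.0000	0.0000	0.0000	0.0000	2.0000
6	0.5000	0.0000	0.5000	0.0000	1.0000
# n_sites = 30
# consensus = CTCGAR
# total_info_bits = 11.0000
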