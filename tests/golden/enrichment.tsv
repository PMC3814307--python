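# motif = CTCGAR
# window = 800
# threshold_fold = 3
# post_ds_timepoints = 18,24,48,Q
# pseudocount = 0.5
# both_strands = True
# ratio_basis = size_factors
# seed = 5
category	k	K	n	N	p_raw	p_corrected
target_process	28	28	45	201	7.8345e-23	7.05105e-22
C01	10	33	45	201	0.166606	1
C02	4	22	45	201	0.774671	1
C03	8	25	45	201	0.163761	1
C04	3	26	45	201	0.961365	1
C05	5	24	45	201	0.664088	1
C06	3	24	45	201	0.941266	1
C07	4	22	45	201	0.774671	1
C08	8	25	45	201	0.163761	1
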