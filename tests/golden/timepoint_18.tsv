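# motif = CTCGAR
# window = 800
# threshold_fold = 3
# post_ds_timepoints = 18,24,48,Q
# pseudocount = 0.5
# both_strands = True
# ratio_basis = size_factors
# seed = 5
gene_id	direction	has_motif	class
XBP1	down	FALSE	none
g053	down	FALSE	none
g001	up	TRUE	direct
g008	up	FALSE	indirect
g009	up	FALSE	indirect
g012	up	FALSE	indirect
g022	up	TRUE	direct
g023	up	TRUE	direct
g033	up	FALSE	indirect
g034	up	TRUE	direct
g042	up	TRUE	direct
g048	up	TRUE	direct
g051	up	TRUE	direct
g055	up	FALSE	indirect
g065	up	TRUE	direct
g070	up	TRUE	direct
g073	up	TRUE	direct
g075	up	FALSE	indirect
g076	up	FALSE	indirect
g083	up	TRUE	direct
g095	up	TRUE	direct
g096	up	FALSE	indirect
g105	up	FALSE	indirect
g110	up	TRUE	direct
g116	up	TRUE	direct
g120	up	TRUE	direct
g127	up	TRUE	direct
g129	up	TRUE	direct
g134	up	TRUE	direct
g149	up	FALSE	indirect
g158	up	FALSE	indirect
g161	up	FALSE	indirect
g166	up	TRUE	direct
g167	up	TRUE	direct
g173	up	TRUE	direct
g175	up	FALSE	indirect
g179	up	FALSE	indirect
g188	up	TRUE	direct
g198	up	TRUE	direct
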