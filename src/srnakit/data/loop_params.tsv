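param	value
hairpin_3	5.40
hairpin_4	5.60
hairpin_5	5.70
hairpin_6	5.40
hairpin_7	6.00
hairpin_8	6.10
hairpin_9	6.20
bulge_1	3.80
bulge_2	2.80
bulge_3	3.20
bulge_4	3.60
bulge_5	4.00
bulge_6	4.40
internal_2	1.50
internal_3	1.60
internal_4	1.70
internal_5	1.80
internal_6	2.00
loop_extrapolation_rt	0.616
multiloop_init	3.40
multiloop_branch	0.40
multiloop_unpaired	0.00
duplex_init	4.10
max_internal_loop	30
duplex_max_loop	6
min_hairpin	3
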