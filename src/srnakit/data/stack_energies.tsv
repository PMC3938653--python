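pair	AU	UA	CG	GC	GU	UG
AU	-0.93	-1.10	-2.24	-2.08	-0.55	-1.36
UA	-1.33	-0.93	-2.35	-2.11	-1.00	-1.27
CG	-2.11	-2.08	-3.26	-2.36	-1.41	-2.11
GC	-2.35	-2.24	-3.42	-3.26	-1.53	-2.51
GU	-1.27	-1.36	-2.51	-2.11	-0.50	0.47
UG	-1.00	-0.55	-1.53	-1.41	-0.57	-0.50
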