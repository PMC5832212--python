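observable	observed	se	min_fluxes	env_moma
glucose_glycogen	1.3	0.3	1.6	1.3
glucose_phb	1.6	0.4	2.0	1.6
glucose_tag	1.1	0.6	0.6	1.4
acetate_glycogen	0.03	0.01	0.0	0.0
acetate_phb	0.90	0.57	0.0	1.1
acetate_tag	0.32	0.21	1.5	0.3
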