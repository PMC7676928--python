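# Active ingredients of Prunella vulgaris passing the OB>=30 / DL>=0.18
# ADME screen, with each compound's degree in the compound-overlapping-target
# (C-OT) network, transcribed from a published network-pharmacology case
# study of Prunella vulgaris against subacute thyroiditis.
compound_id	name	ob	dl	cot_degree
MOL000098	Quercetin	46.43	0.28	68
MOL000422	Kaempferol	41.88	0.24	37
MOL000006	Luteolin	36.16	0.25	32
MOL000358	Beta-sitosterol	36.91	0.75	27
MOL000449	Stigmasterol	43.83	0.76	24
MOL000737	Morin	46.23	0.27	16
MOL004798	Delphinidin	40.63	0.28	11
MOL004355	Spinasterol	42.98	0.76	5
MOL006767	Vulgaxanthin-I	56.14	0.26	4
MOL006772	Poriferasterol monoglucoside_qt	43.83	0.76	4
MOL006774	Stigmast-7-enol	37.42	0.75	3
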