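# Hub targets of the high-confidence (score >= 0.7) PPI network among the
# 83 therapeutic targets, with degree (DC) and normalized betweenness (BC),
# transcribed from a published network-pharmacology case study of Prunella
# vulgaris against subacute thyroiditis. Gene symbols normalized (IL-1β -> IL1B).
node	dc	bc
TP53	33	0.146655
IL6	32	0.103348
JUN	30	0.076404
MAPK1	30	0.062201
MAPK8	29	0.089256
TNF	28	0.057882
VEGFA	27	0.065223
EGF	23	0.053058
IL1B	22	0.009747
PTGS2	22	0.044508
APP	21	0.191657
EGFR	20	0.021937
ESR1	19	0.028738
CCL2	19	0.013005
MAPK14	17	0.004943
AR	17	0.026691
HMOX1	16	0.01145
NOS3	15	0.003683
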