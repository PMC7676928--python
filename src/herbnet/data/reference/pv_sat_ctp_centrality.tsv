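# Per-node degree (DC) and normalized betweenness (BC) of the tripartite
# compound-target-pathway (C-T-P) network, transcribed from a published
# network-pharmacology case study of Prunella vulgaris against subacute
# thyroiditis: 11 compounds, 34 targets, 20 pathways.
node	kind	dc	bc
Quercetin	compound	29	0.28053366
Luteolin	compound	18	0.09443417
Kaempferol	compound	16	0.07144764
Beta-sitosterol	compound	12	0.05629246
Stigmasterol	compound	8	0.02265721
Morin	compound	7	0.01050266
Delphinidin	compound	6	0.00842733
Vulgaxanthin-I	compound	2	0.000168
Spinasterol	compound	1	0
Poriferasterol monoglucoside_qt	compound	1	0
Stigmast-7-enol	compound	1	0
PIK3CG	target	19	0.101838
MAPK1	target	17	0.066987
MAPK14	target	16	0.068118
TNF	target	12	0.039517
PTGS2	target	11	0.044665
ESR1	target	11	0.107751
JUN	target	10	0.025135
NOS2	target	10	0.039108
MAPK8	target	9	0.016002
EGFR	target	9	0.025645
GSK3B	target	9	0.019636
CDK2	target	9	0.025971
BCL2	target	8	0.019616
NOS3	target	8	0.022166
TP53	target	8	0.021252
IL6	target	7	0.010758
VEGFA	target	7	0.009984
EGF	target	6	0.007181
IFNG	target	5	0.005949
VCAM1	target	4	0.003979
CDK4	target	4	0.004304
IL2	target	4	0.002602
MET	target	4	0.002161
CHEK1	target	4	0.006204
HTR2A	target	4	0.004661
CCL2	target	3	0.001973
SELE	target	3	0.001084
MMP2	target	3	0.002267
CDK1	target	3	0.003758
PLAU	target	3	0.00391
ADRA1A	target	3	0.001579
MMP3	target	2	0.000495
CTSD	target	2	0.000658
PTGER3	target	2	0.002331
PI3K-Akt signaling pathway	pathway	14	0.042792
TNF signaling pathway	pathway	12	0.0336
HIF-1 signaling pathway	pathway	10	0.018361
T Cell receptor signaling pathway	pathway	9	0.015969
Sphingolipid signaling pathway	pathway	9	0.018039
MAPK signaling pathway	pathway	8	0.010468
Toll-like receptor signaling pathway	pathway	7	0.005861
Rap1 signaling pathway	pathway	7	0.008431
Ras signaling pathway	pathway	7	0.009325
NOD-like receptor signaling pathway	pathway	6	0.005763
VEGF signaling pathway	pathway	6	0.005997
GnRH signaling pathway	pathway	6	0.006022
Calcium signaling pathway	pathway	6	0.012494
p53 signaling pathway	pathway	5	0.004671
NF-kappa B signaling pathway	pathway	5	0.004721
Thyroid hormone signaling pathway	pathway	5	0.007399
Apoptosis	pathway	4	0.002136
B-cell receptor signaling pathway	pathway	4	0.001427
Natural killer cell mediated cytotoxicity	pathway	4	0.002105
Inflammatory mediator regulation of TRP channels	pathway	4	0.006817
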