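# alias	canonical
# Built-in gene-symbol alias table: common legacy/protein names mapped to
# HGNC symbols. Entries are normalized (Greek transliterated, hyphens
# removed, uppercased) before lookup, so COX-2 and COX2 both resolve.
COX2	PTGS2
COX1	PTGS1
INOS	NOS2
ENOS	NOS3
TNFALPHA	TNF
TNFA	TNF
IL1BETA	IL1B
IL1F2	IL1B
P53	TP53
ERK2	MAPK1
ERK1	MAPK3
JNK1	MAPK8
P38	MAPK14
VEGF	VEGFA
MCP1	CCL2
HO1	HMOX1
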