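class_name	gene_symbol
canonical_H2A	HIST1H2AA
canonical_H2A	HIST1H2AB
canonical_H2A	HIST1H2AC
canonical_H2A	HIST1H2AD
canonical_H2A	HIST1H2AE
canonical_H2A	HIST1H2AG
canonical_H2A	HIST1H2AH
canonical_H2A	HIST1H2AI
canonical_H2A	HIST1H2AJ
canonical_H2A	HIST1H2AK
canonical_H2A	HIST1H2AL
canonical_H2A	HIST1H2AM
canonical_H2A	HIST2H2AB
canonical_H2A	HIST2H2AC
canonical_H2A	HIST3H2A
canonical_H2B	HIST1H2BA
canonical_H2B	HIST1H2BB
canonical_H2B	HIST1H2BC
canonical_H2B	HIST1H2BD
canonical_H2B	HIST1H2BE
canonical_H2B	HIST1H2BF
canonical_H2B	HIST1H2BG
canonical_H2B	HIST1H2BH
canonical_H2B	HIST1H2BI
canonical_H2B	HIST1H2BJ
canonical_H2B	HIST1H2BK
canonical_H2B	HIST1H2BL
canonical_H2B	HIST1H2BM
canonical_H2B	HIST1H2BN
canonical_H2B	HIST1H2BO
canonical_H2B	HIST2H2BE
canonical_H2B	HIST2H2BF
canonical_H2B	HIST3H2BB
FP_GC_panel	HIST1H1B
FP_GC_panel	HIST1H1C
FP_GC_panel	HIST1H1D
FP_GC_panel	HIST1H1E
FP_GC_panel	HIST1H2AC
FP_GC_panel	HIST1H2BJ
FP_GC_panel	B2M
FP_GC_panel	CD58
FP_GC_panel	CD70
FP_GC_panel	PIK3CA
FP_GC_panel	PIK3R1
FP_GC_panel	NFKBIA
FP_GC_panel	NFKBIE
FP_GC_panel	CARD11
FP_GC_panel	JAK2
FP_GC_panel	STAT3
FP_GC_panel	KRAS
FP_GC_panel	NRAS
FP_GC_panel	BRAF
chromatin_modifier_panel	EZH2
chromatin_modifier_panel	CREBBP
chromatin_modifier_panel	EP300
chromatin_modifier_panel	KMT2D
chromatin_modifier_panel	BCL11A
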