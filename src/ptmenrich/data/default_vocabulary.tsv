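level	label	parent_labels
KW	Phosphoprotein
KW	Glycoprotein
KW	Disulfide bond
KW	Nucleotide-binding
KW	Acetylation
KW	Lipoprotein
KW	Methylation
KW	Ubl conjugation
KW	Amidation
KW	Citrullination
KW	Sulfation
KW	Hydroxylation
KW	Palmitoylation
KW	Pyridoxal phosphate
KW	D-amino acid
KW	Isopeptide bond
FT	Phosphoserine	Phosphoprotein
FT	Phosphothreonine	Phosphoprotein
FT	Phosphotyrosine	Phosphoprotein
FT	Phosphohistidine	Phosphoprotein
FT	N6-acetyllysine	Acetylation
FT	N-acetylalanine	Acetylation
FT	N-acetylmethionine	Acetylation
FT	N6-succinyllysine	Acetylation
FT	N-linked (GlcNAc...) asparagine	Glycoprotein
FT	O-linked (GalNAc...) threonine	Glycoprotein
FT	S-palmitoyl cysteine	Lipoprotein|Palmitoylation
FT	N-palmitoyl cysteine	Lipoprotein|Palmitoylation
FT	S-diacylglycerol cysteine	Lipoprotein
FT	N6-(pyridoxal phosphate)lysine	Pyridoxal phosphate
FT	N6-carboxylysine	Hydroxylation
FT	N5-methylglutamine	Methylation
FT	Omega-N-methylarginine	Methylation
FT	Citrulline	Citrullination
FT	Sulfotyrosine	Sulfation
FT	4-hydroxyproline	Hydroxylation
FT	Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)	Ubl conjugation|Isopeptide bond
FT	Cysteine persulfide	Disulfide bond
FT	D-4-hydroxyvaline	D-amino acid
FT	D-valine	D-amino acid
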