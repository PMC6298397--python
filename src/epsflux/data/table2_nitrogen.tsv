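substrate	in_vivo	in_silico
Urea	-	+
NH4Cl	+	+
L-Methionine	-	-
L-Isoleucine	+	+
L-Leucine	+	+
L-Phenylalanine	+	+
L-Proline	+	+
L-Alanine	+	+
L-Glutamate	+	+
L-Glutamine	+	+
L-Glycine	+	+
L-Threonine	+	+
L-Aspartate	+	+
L-Asparagine	+	+
L-Tryptophan	+	+
L-Histidine	+	+
L-Serine	+	+
L-Tyrosine	+	+
L-Valine	+	+
L-Lysine	+	+
L-Arginine	+	+
L-Cysteine	+	+
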