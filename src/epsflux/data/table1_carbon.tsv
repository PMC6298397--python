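substrate	in_vivo	in_silico
Glucose	+	+
Sucrose	+	+
Galactose	+	+
Mannose	+	+
Xylose	+	+
Maltose	+	+
Lactose	+	+
Fructose	+	+
Arabinose	+	+
Mannitol	+	+
Cellobiose	+	+
Starch	+	+
Fucose	+	+
Rhamnose	+	+
Inositol	-	-
Ethanol	+	+
Citrate	-	+
Malate	+	+
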