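# Mini KEGG-style reference definitions for the pathways of the coverage table.
# Compound sets are the pathway's reported metabolite columns (mapped to KEGG
# C-numbers) plus canonical undetected intermediates; enzyme sets are the
# eight citrate-cycle ECs, the ten canonical glycolytic ECs, and small
# plausible sets elsewhere. This is an editable, package-local reference, not
# a KEGG database export.
pathway_id	name	compounds	enzymes	reactions
ath00010	Glycolysis / Gluconeogenesis	C00022;C00031;C00186;C00074;C00118;C00631;C00024	2.7.1.1;5.3.1.9;2.7.1.11;4.1.2.13;5.3.1.1;1.2.1.12;2.7.2.3;5.4.2.12;4.2.1.11;2.7.1.40
ath00020	Citrate cycle (TCA cycle)	C00022;C00042;C00122;C00149;C00158;C00417;C00024;C00026;C00036;C00074;C00091;C00311	2.3.3.1;4.2.1.3;1.1.1.42;1.2.4.2;6.2.1.4;1.3.5.1;4.2.1.2;1.1.1.37	2.3.3.1:C00036>C00158;4.2.1.3:C00158>C00417;4.2.1.3:C00417>C00311;1.1.1.42:C00311>C00026;1.2.4.2:C00026>C00091;6.2.1.4:C00091>C00042;1.3.5.1:C00042>C00122;4.2.1.2:C00122>C00149;1.1.1.37:C00149>C00036
ath00030	Pentose phosphate pathway	C00022;C00031;C00198;C00258;C00199;C00117	1.1.1.49;3.1.1.31;1.1.1.44;5.3.1.6;2.2.1.1;2.2.1.2
ath00052	Galactose metabolism	C00031;C00089;C00095;C00116;C00124;C00137;C00794;C00880;C05402;C00492;C00052;C00243	3.2.1.22;2.7.1.6;5.1.3.2;3.2.1.26
ath00250	Alanine, aspartate and glutamate metabolism	C00022;C00025;C00041;C00042;C00049;C00122;C00152;C00158;C00334;C00026;C00064;C00036	2.6.1.1;2.6.1.2;1.4.1.3;6.3.5.4;4.1.1.15;6.3.1.2
ath00260	Glycine, serine and threonine metabolism	C00022;C00049;C00065;C00188;C00258;C00037;C00263	2.1.2.1;1.1.1.95;2.7.2.4;4.3.1.19
ath00270	Cysteine and methionine metabolism	C00022;C00041;C00049;C00065;C00073;C00097;C00019	2.5.1.47;2.1.1.14;2.5.1.6;4.4.1.8
ath00360	Phenylalanine metabolism	C00022;C00042;C00079;C00122;C00805;C00423;C00166	4.3.1.24;2.6.1.57;1.11.1.7
ath00500	Starch and sucrose metabolism	C00031;C00089;C00092;C00095;C00185;C00208;C00718;C00029;C01083	2.4.1.13;2.4.1.14;3.2.1.26;2.4.1.1;2.7.1.1;5.3.1.9
ath00520	Amino sugar and nucleotide sugar metabolism	C00031;C00259;C00333;C00029;C00096;C00140	2.7.7.9;5.1.3.2;2.7.1.1
ath00630	Glyoxylate and dicarboxylate metabolism	C00022;C00025;C00042;C00065;C00149;C00158;C00160;C00209;C00258;C00417	4.1.3.1;2.3.3.9;1.1.1.37;4.2.1.3
ath00710	Carbon fixation in photosynthetic organisms	C00022;C00041;C00049;C00149;C00197;C01182	4.1.1.39;1.2.1.13;2.7.2.3;4.1.1.31
ath00940	Phenylpropanoid biosynthesis	C00079;C00627;C00423;C00811	4.3.1.24;1.11.1.7;2.3.1.133;1.1.1.195
ath01040	Biosynthesis of unsaturated fatty acids	C00249;C00712;C01530;C01595;C06427;C00219	1.14.19.1;1.14.19.22;3.1.2.14
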