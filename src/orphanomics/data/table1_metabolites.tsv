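# GC-MS metabolite identifications with KEGG compound ids and chemical families.
# 61 named entries are carried as printed in the source identification table,
# although its accompanying text reports "a total of 62 compounds"; the
# discrepancy is preserved, not reconciled.
name	kegg_id	family	synonyms
L-Glutamate	C00025	amino acids	glutamate
L-aspartate	C00049	amino acids	aspartate
L-alanine	C00041	amino acids	alanine
L-asparagine	C00152	amino acids	asparagine
L-serine	C00065	amino acids	serine
L-threonine	C00188	amino acids	threonine
L-leucine	C00123	amino acids	leucine
L-valine	C00183	amino acids	valine
L-isoleucine	C00407	amino acids	isoleucine
L-proline	C00148	amino acids	proline
L-phenylalanine	C00079	amino acids	phenylalanine
Ascorbate	C00072	organic acids	ascorbic acid
pyruvate	C00022	organic acids	pyruvic acid
L-lactate	C00186	organic acids	lactate
succinate	C00042	organic acids	succinic acid
fumarate	C00122	organic acids	fumaric acid
malate	C00149	organic acids	malic acid
citrate	C00158	organic acids	citric acid
aconitate	C00417	organic acids	cis-aconitate
gluconolactone	C00198	organic acids	D-glucono-1,5-lactone
D-glycerate	C00258	organic acids	glycerate
glucarate	C00818	organic acids	D-glucarate
galactarate	C00879	organic acids	mucic acid
maleate	C01384	organic acids	maleic acid
salicylate	C00805	organic acids	salicylic acid
pyroglutamic acid	C01879	organic acids	pyroglutamate
oxalate	C00209	organic acids	oxalic acid
gallate	C00627	organic acids	gallic acid
quinate	C00296	organic acids	quinic acid
D-ribonate	C01685	organic acids	ribonate
D-Glucose	C00031	carbohydrates	glucose
L-arabinose	C00259	carbohydrates	arabinose
D-xylulose	C00310	carbohydrates	xylulose
D-galacturonate	C00333	carbohydrates	galacturonate
D-fructose	C00095	carbohydrates	fructose
L-sorbose	C00247	carbohydrates	sorbose
mannitol	C00392	carbohydrates	D-mannitol
L-rhamnose	C00507	carbohydrates	rhamnose
D-sorbitol	C00794	carbohydrates	sorbitol
sucrose	C00089	carbohydrates
D-galactose	C00124	carbohydrates	galactose
melibiose	C05402	carbohydrates
myo-inositol	C00137	carbohydrates	inositol
D-glucose 6-phosphate	C00092	carbohydrates	glucose 6-phosphate
maltose	C00208	carbohydrates	D-maltose
maltotriose	C01835	carbohydrates
D-cellobiose	C00185	carbohydrates	cellobiose
D-galactonate	C00880	carbohydrates	galactonate
D-erythrose	C01796	carbohydrates	erythrose
Glycerol	C00116	polyols
viburnitol	C08259	polyols
Palmitic acid	C00249	fatty acids	palmitate
oleic acid	C00712	fatty acids	oleate
stearic acid	C01530	fatty acids	stearate
linoleic acid	C01595	fatty acids	linoleate
Catechin	C06562	phenolic compounds	(+)-catechin
epigallocatechin	C12136	phenolic compounds
Urea	C00086	others
4-aminobutanoate (GABA)	C00334	others	4-aminobutanoate;GABA;gamma-aminobutyrate
tridecane	C13834	others
anthraquinone	C16207	others
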