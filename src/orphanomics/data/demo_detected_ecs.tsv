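# Synthetic demo detection sets (constructed, not measured data).
# Protein layer: 6 of the 8 citrate-cycle enzymes (succinate dehydrogenase
# 1.3.5.1 and alpha-ketoglutarate dehydrogenase 1.2.4.2 undetected) and 8 of
# the 10 glycolytic enzymes (phosphofructokinase 2.7.1.11 and
# phosphoglycerate mutase 5.4.2.12 undetected).  Transcript layer: all of
# both pathways plus a few enzymes of neighbouring pathways.
layer	ec
protein	2.3.3.1
protein	4.2.1.3
protein	1.1.1.42
protein	6.2.1.4
protein	4.2.1.2
protein	1.1.1.37
protein	2.7.1.1
protein	5.3.1.9
protein	4.1.2.13
protein	5.3.1.1
protein	1.2.1.12
protein	2.7.2.3
protein	4.2.1.11
protein	2.7.1.40
protein	2.4.1.13
protein	2.6.1.1
transcript	2.3.3.1
transcript	4.2.1.3
transcript	1.1.1.42
transcript	1.2.4.2
transcript	6.2.1.4
transcript	1.3.5.1
transcript	4.2.1.2
transcript	1.1.1.37
transcript	2.7.1.1
transcript	5.3.1.9
transcript	2.7.1.11
transcript	4.1.2.13
transcript	5.3.1.1
transcript	1.2.1.12
transcript	2.7.2.3
transcript	5.4.2.12
transcript	4.2.1.11
transcript	2.7.1.40
transcript	2.4.1.13
transcript	2.6.1.1
transcript	6.3.1.2
transcript	4.3.1.24
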