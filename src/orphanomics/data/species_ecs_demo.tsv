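# Small fictional five-species enzyme sets for demonstrating the Venn
# partition; synthetic fixture, not derived from any reference proteome.
species	ecs
speciesA	1.1.1.1;2.7.1.1;2.7.1.40;4.2.1.2;4.2.1.3;1.1.1.37;2.3.3.1;6.2.1.4
speciesB	1.1.1.1;2.7.1.1;2.7.1.40;4.2.1.2;4.2.1.3;1.1.1.37;5.3.1.9;3.2.1.22
speciesC	1.1.1.1;2.7.1.1;2.7.1.40;4.2.1.3;1.1.1.37;2.6.1.1;1.4.1.3
speciesD	1.1.1.1;2.7.1.1;4.2.1.2;1.1.1.37;2.4.1.13;2.4.1.14
speciesE	1.1.1.1;2.7.1.40;4.2.1.3;6.3.1.2;4.1.1.15
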