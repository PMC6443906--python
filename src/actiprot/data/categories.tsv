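category	description
mitochondrion	Mitochondrial proteins incl. oxidative phosphorylation and fatty-acid oxidation
tca_cycle	Tricarboxylic acid cycle enzymes
spliceosome	Spliceosomal and mRNA-splicing proteins
immune	Immune response and inflammatory mediators
proteostasis	Autophagy, chaperones, ubiquitin-proteasome system
dna_damage_repair	DNA damage response and repair
senescence	Cellular senescence markers
other	No curated category
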