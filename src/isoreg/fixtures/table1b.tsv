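# Ten most downregulated cerebral-artery proteins 48 h after SAH (vehicle vs sham).
# Values are log2 iTRAQ reporter ratios as published.
accession	name	log2
Q62715	Neutrophil antibiotic peptide NP-2	-5.38
P04764	Alpha-enolase	-5.38
D3ZLY9	Histone H2B type 1-H	-4.82
P05811	Alpha-crystallin B chain	-4.47
Q5RKG9	Eukaryotic translation initiation factor 4B	-4.09
Q6LED0	Histone H3.1	-3.96
P04646	60S ribosomal protein L35a	-3.85
P08081	Clathrin light chain A	-3.75
P08009	Glutathione S-transferase Yb-3	-3.64
Q9JM53	Apoptosis-inducing factor 1, mitochondrial	-3.42
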