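# Group 2: proteins downregulated 48 h after SAH (vehicle vs sham) whose
# downregulation does not persist under the MEK1/2 inhibitor U0126. Values are
# log2 iTRAQ ratios.
# Transcribed verbatim. The published group size is stated as 51 proteins, but the
# published table text contains only 50 data rows; the missing row is not
# recoverable from the source.
accession	name	log2
Q64478	Histone H2B type 1-H	-4.82
P05811	Alpha-crystallin B chain	-4.47
Q8BGD9	Eukaryotic translation initiation factor 4B	-4.09
P08009	Glutathione S-transferase Yb-3	-3.64
Q5U2R0	Methionine adenosyltransferase 2 subunit beta	-3.39
P62860	40S ribosomal protein S30	-3.29
P23457	3-Alpha-hydroxysteroid dehydrogenase	-3.25
Q9Z2G8	Nucleosome assembly protein 1-like 1	-3.14
P55063	Heat shock 70 kDa protein 1-like	-3.03
Q8VDM6	Heterogeneous nuclear ribonucleoprotein U-like protein 1	-2.93
P22057	Prostaglandin-H2 D-isomerase	-2.87
P04897	Guanine nucleotide-binding protein G(i) subunit alpha-2	-2.76
P27321	Calpastatin	-2.76
Q04940	Neurogranin	-2.72
O35206	Collagen alpha-1(XV) chain	-2.72
Q9CSU0	Regulation of nuclear pre-mRNA domain-containing protein 1B	-2.39
Q63362	NADH dehydrogenase [ubiquinone] 1 alpha subcomplex subunit 5	-2.32
Q63768	Adapter molecule crk	-2.32
P26043	Radixin	-2.23
Q63584	Transmembrane protein Tmp21	-2.20
P27274	CD59 glycoprotein	-2.18
Q3T1I4	Protein PRRC1	-2.16
P62142	Serine/threonine-protein phosphatase PP1-beta catalytic subunit	-2.15
P55002	Microfibrillar-associated protein 2	-1.39
Q04857	Collagen alpha-1(VI) chain	-1.36
P04157	Receptor-type tyrosine-protein phosphatase C	-1.22
P11240	Cytochrome c oxidase subunit 5A, mitochondrial	-1.22
P15508	Spectrin beta chain, erythrocyte	-1.20
P31399	ATP synthase subunit d, mitochondrial	-1.15
Q62737	Cytochrome b-245 light chain	-1.10
Q02788	Collagen alpha-2(VI) chain	-1.09
P26051	CD44 antigen	-1.08
Q8BUR4	Dedicator of cytokinesis protein 1	-1.06
P11662	NADH-ubiquinone oxidoreductase chain 2	-1.03
P24623	Alpha-crystallin A chain	-1.03
P61805	Dolichyl-diphosphooligosaccharide--protein glycosyltransferase subunit DAD1	-0.95
P97700	Mitochondrial 2-oxoglutarate/malate carrier protein	-0.90
Q9JM51	Prostaglandin E synthase	-0.88
Q6AXX6	UPF0765 protein C10orf58 homolog	-0.87
P26151	High affinity immunoglobulin gamma Fc receptor I	-0.86
Q9R233	Tapasin	-0.85
Q9CQ91	NADH dehydrogenase [ubiquinone] 1 alpha subcomplex subunit 3	-0.84
P29419	ATP synthase subunit e, mitochondrial	-0.83
Q3B8Q1	Nucleolar RNA helicase 2	-0.83
P06687	Sodium/potassium-transporting ATPase subunit alpha-3	-0.80
P97544	Lipid phosphate phosphohydrolase 3	-0.79
P00697	Lysozyme C-1	-0.77
P11247	Myeloperoxidase	-0.77
P08050	Gap junction alpha-1 protein	-0.77
Q99P82	Claudin-11	-0.77
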