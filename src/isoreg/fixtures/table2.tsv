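# Group 1: proteins upregulated 48 h after SAH (vehicle vs sham) whose upregulation
# does not persist under the MEK1/2 inhibitor U0126. Values are log2 iTRAQ ratios.
# Transcribed verbatim. The published group size is stated as 133 proteins, but the
# published table text contains 139 data rows: accessions Q4FZY0, P63326, P97633 and
# Q63560 are each listed twice with different log2 values (135 distinct accessions).
# The verbatim rows are preserved; consumers that need distinct proteins must
# deduplicate explicitly.
accession	name	log2
Q9JJ54	Heterogeneous nuclear ribonucleoprotein D0	3.84
Q4FZY0	EF-hand domain-containing protein D2	3.78
Q9Z1Z3	Epsin-2	3.78
Q925G0	Putative RNA-binding protein 3	3.74
B3EWD2	Hemoglobin subunit beta	3.70
B5DFF2	RNA-binding protein with multiple splicing 2	3.70
Q9DBR1	5'-3' Exoribonuclease 2	3.58
Q63083	Nucleobindin-1	3.58
P11348	Dihydropteridine reductase	3.57
P63281	SUMO-conjugating enzyme UBC9	3.55
Q8BQ30	Phostensin	3.54
Q6P686	Osteoclast-stimulating factor 1	3.52
Q63797	Proteasome activator complex subunit 1	3.46
Q8K297	Procollagen galactosyltransferase 1	3.45
Q4KM73	UMP-CMP kinase	3.41
Q924S5	Lon protease homolog, mitochondrial	3.38
Q9QX47	Protein SON	3.34
Q5U318	Astrocytic phosphoprotein PEA-15	3.33
P61149	Fibroblast growth factor 1	3.28
Q5BJK8	Golgi integral membrane protein 4	3.28
O08586	Phosphatidylinositol-3,4,5-trisphosphate 3-phosphatase	3.25
D3ZQN7	Laminin subunit beta-1	3.22
P62815	V-type proton ATPase subunit B, brain isoform	3.22
Q9DBZ5	Eukaryotic translation initiation factor 3 subunit K	3.16
P61972	Nuclear transport factor 2	3.15
Q4FZY0	EF-hand domain-containing protein D2	3.13
Q6PEV3	WAS/WASL-interacting protein family member 2	3.11
P63326	40S ribosomal protein S10	3.10
Q6AY09	Heterogeneous nuclear ribonucleoprotein H2	3.03
Q63663	Interferon-induced guanylate-binding protein 2	3.02
P52303	AP-1 complex subunit beta-1	2.97
P60868	40S ribosomal protein S20	2.97
Q64611	Cysteine sulfinic acid decarboxylase	2.90
P51583	Multifunctional protein ADE2	2.89
Q63871	DNA-directed RNA polymerases I, II, and III subunit RPABC4	2.89
Q5U211	Sorting nexin-3	2.87
P27615	Lysosome membrane protein 2	2.86
Q4KM65	Cleavage and polyadenylation specificity factor subunit 6	2.86
Q62865	cGMP-inhibited 3',5'-cyclic phosphodiesterase A	2.85
P55260	Annexin A4	2.84
Q8R361	Rab11 family-interacting protein 5	2.81
P97379	Ras GTPase-activating protein-binding protein 2	2.81
Q66H20	Polypyrimidine tract-binding protein 2	2.78
Q6AXS3	Protein DEK	2.72
P36876	Serine/threonine-protein phosphatase 2A 55 kDa regulatory subunit B alpha isoform	2.72
B5DFC8	Eukaryotic translation initiation factor 3 subunit C	2.72
Q9QWE9	Gamma-glutamyltransferase 5	2.71
Q63433	Serine/threonine-protein kinase N1	2.70
Q4KM74	Vesicle-trafficking protein SEC22b	2.69
Q5U2T8	Corepressor interacting with RBPJ 1	2.64
Q9WVA3	Mitotic checkpoint protein BUB3	2.61
Q8CIE6	Coatomer subunit alpha	2.59
G3V9C7	Histone H2B type 1-K	2.57
Q9Z340	Partitioning defective 3 homolog	2.55
P97633	Casein kinase I isoform alpha	2.47
P41499	Tyrosine-protein phosphatase non-receptor type 11	2.46
P60711	Actin, cytoplasmic 1	2.45
Q9R1Z8	Vinexin	2.45
Q63560	Microtubule-associated protein 6	2.42
Q27W02	Protein mago nashi homolog	2.39
Q6AYD6	PDZ and LIM domain protein 2	2.37
Q4AEF8	Coatomer subunit gamma	2.37
P52481	Adenylyl cyclase-associated protein 2	2.37
P49138	MAP kinase-activated protein kinase 2	2.36
Q99P96	Histone deacetylase 7	2.36
P36372	Antigen peptide transporter 2	2.35
P05811	Alpha-crystallin B chain	2.34
Q5HZV9	Protein phosphatase 1 regulatory subunit 7	2.33
P70615	Lamin-B1	2.32
Q9WUX5	Protein MRVI1	2.32
P16675	Lysosomal protective protein	2.31
Q9EPH8	Polyadenylate-binding protein 1	2.29
Q63560	Microtubule-associated protein 6	2.28
Q60436	Serrate RNA effector molecule homolog (Fragment)	2.26
Q8R081	Heterogeneous nuclear ribonucleoprotein L	2.26
Q561S0	NADH dehydrogenase [ubiquinone] 1 alpha subcomplex subunit 10, mitochondrial	2.26
Q5U2R0	Methionine adenosyltransferase 2 subunit beta	2.24
P46664	Adenylosuccinate synthetase isozyme 2	2.21
P0C5W1	Microtubule-associated protein 1S	2.19
Q9WTT6	Guanine deaminase	2.17
O55125	Protein NipSnap homolog 1	2.17
Q6MG49	Large proline-rich protein BAG6	2.16
P04692	Tropomyosin alpha-1 chain	2.16
Q8VC85	U6 snRNA-associated Sm-like protein LSm1	2.16
Q6AYE2	Endophilin-B1	2.16
D3ZU13	Eukaryotic translation initiation factor 4 gamma 1	2.15
Q6MG61	Chloride intracellular channel protein 1	2.14
O55012	Phosphatidylinositol-binding clathrin assembly protein	2.13
Q5U301	A-kinase anchor protein 2	2.13
Q9Z2K1	Keratin, type I cytoskeletal 16	2.13
Q9EPL8	Importin-7	2.10
P14426	H-2 class I histocompatibility antigen, D-K alpha chain	2.06
Q8BSY0	Aspartyl/asparaginyl beta-hydroxylase	2.05
Q6AYQ4	Transmembrane protein 109	2.02
O55096	Dipeptidyl peptidase 3	2.01
P39069	Adenylate kinase isoenzyme 1 (Fragments)	1.98
P05982	NAD(P)H dehydrogenase [quinone] 1	1.34
Q9QXQ0	Alpha-actinin-4	1.27
Q62507	Cochlin	1.26
P19132	Ferritin heavy chain	1.20
P38983	40S ribosomal protein SA	1.17
P52944	PDZ and LIM domain protein 1	1.17
P70619	Glutathione reductase (Fragment)	1.14
P24368	Peptidyl-prolyl cis-trans isomerase B	1.12
P38652	Phosphoglucomutase-1	1.07
P63326	40S ribosomal protein S10	1.06
Q5XI28	Ribonucleoprotein PTB-binding 1	1.05
Q9Z1P2	Alpha-actinin-1	1.05
B0BNF1	Septin-8	1.04
P97633	Casein kinase I isoform alpha	1.04
P63102	14-3-3 protein zeta/delta	1.03
Q60972	Histone-binding protein RBBP4	0.99
Q9DB16	Calcium-binding protein 39-like	0.96
Q497B0	Omega-amidase NIT2	0.96
B0BNA7	Eukaryotic translation initiation factor 3 subunit I	0.95
P47853	Biglycan	0.94
Q921M3	Splicing factor 3B subunit 3	0.93
O55126	Protein NipSnap homolog 2	0.93
Q8VHI3	GDP-fucose protein O-fucosyltransferase 2	0.92
P61983	14-3-3 protein gamma	0.91
P28661	Septin-4	0.89
P14046	Alpha-1-inhibitor 3	0.88
P15651	Short-chain specific acyl-CoA dehydrogenase, mitochondrial	0.87
P19804	Nucleoside diphosphate kinase B	0.86
P85972	Vinculin	0.85
P15865	Histone H1.2	0.84
Q58FK9	Kynurenine--oxoglutarate transaminase 3	0.84
P62260	14-3-3 protein epsilon	0.84
Q5XI78	2-Oxoglutarate dehydrogenase, mitochondrial	0.82
B2GV06	Succinyl-CoA:3-ketoacid-coenzyme A transferase 1, mitochondrial	0.82
P31977	Ezrin	0.81
Q01129	Decorin	0.80
O88483	[Pyruvate dehydrogenase [acetyl-transferring]]-phosphatase 1, mitochondrial	0.80
P18418	Calreticulin	0.80
P12007	Isovaleryl-CoA dehydrogenase, mitochondrial	0.79
O35854	Branched-chain-amino-acid aminotransferase, mitochondrial	0.78
Q66HS7	PDZ and LIM domain protein 3	0.78
P07335	Creatine kinase B-type	0.77
Q9ESW0	DNA damage-binding protein 1	0.77
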