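# Ten most upregulated cerebral-artery proteins 48 h after SAH (vehicle vs sham).
# Values are log2 iTRAQ reporter ratios as published.
# Transcription note: the S100-A9 value prints run together with the next row's
# accession ('3.969JJ54...'); transcribed as 3.96 with the following accession
# Q9JJ54 (confirmed by the group-1 table, where that row reappears).
accession	name	log2
P50116	Protein S100-A9	3.96
Q9JJ54	Heterogeneous nuclear ribonucleoprotein D0	3.84
Q9Z1Z3	Epsin-2	3.78
Q925G0	Putative RNA-binding protein 3	3.74
B3EWD2	Hemoglobin subunit beta	3.70
Q8VC52	RNA-binding protein with multiple splicing 2	3.70
Q9DBR1	5'-3' Exoribonuclease 2	3.58
Q63083	Nucleobindin-1	3.58
P11348	Dihydropteridine reductase	3.57
P63281	SUMO-conjugating enzyme UBC9	3.55
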