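# SYNTHETIC demo interaction edges among packaged group-table proteins,
# constructed by hand for examples and tests (mirrors the kinds of clusters the
# study described: structural, 14-3-3 adaptor, translation, reductase,
# mitochondrial-metabolic, immune). Not a STRING export; scores illustrative.
# Format: accession_a<TAB>accession_b<TAB>score in [0,1].
Q9Z1P2	P85972	0.92
Q9QXQ0	P85972	0.90
Q9Z1P2	P60711	0.95
Q9QXQ0	P60711	0.93
P60711	P04692	0.96
P85972	P60711	0.91
P31977	P60711	0.62
P63102	P61983	0.94
P63102	P62260	0.93
P61983	P62260	0.92
P63102	Q9QXQ0	0.35
B5DFC8	B0BNA7	0.97
B5DFC8	Q9DBZ5	0.96
B0BNA7	Q9DBZ5	0.95
Q9EPH8	B5DFC8	0.71
Q9EPH8	P63326	0.68
Q9Z1Z3	O55012	0.81
P05982	P70619	0.55
P31399	P29419	0.89
P31399	P11240	0.74
P29419	P11240	0.70
Q63362	Q9CQ91	0.88
Q63362	P11240	0.77
P11247	P26151	0.66
P26151	P27274	0.52
P26151	Q9R233	0.31
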