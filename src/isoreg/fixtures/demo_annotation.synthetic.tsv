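# SYNTHETIC demo annotation: molecular-function categories for a subset of the
# packaged group-table proteins, constructed by hand for examples and tests.
# Not a database export; category assignments are illustrative only.
# Format: accession<TAB>semicolon-joined categories.
P63102	binding
P61983	binding
P62260	binding
Q9QXQ0	structural activity;binding
Q9Z1P2	structural activity;binding
P85972	structural activity
P04692	structural activity
P60711	structural activity
P31977	structural activity
Q9Z1Z3	binding
O55012	binding
Q9EPH8	binding;translation
B5DFC8	translation
B0BNA7	translation
Q9DBZ5	translation
P63326	translation;structural activity
P05982	catalytic activity
P70619	catalytic activity
P07335	catalytic activity
P19132	transporter;binding
P36372	transporter
P41499	catalytic activity;enzyme regulator activity
Q99P96	catalytic activity;transcription factor activity
P31399	catalytic activity;transporter
P29419	catalytic activity;transporter
P11240	catalytic activity
Q63362	catalytic activity
Q9CQ91	catalytic activity
P11247	catalytic activity
P26151	receptor activity;binding
P27274	receptor activity
P26051	receptor activity;binding
Q9R233	binding
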