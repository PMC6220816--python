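# Gene x functional-area association grid for the 22 most consistently
# implicated persisting-pain genes (1 = gene annotated under the headline
# term's descendant closure, 0 = not). n_settings = number of distinct
# clinical settings with a positive report.
gene	n_settings	response_to_stimulus	immune_system_process	reactive_oxygen_species_metabolic_process	transport	neurological_system_process	regulation_of_multicellular_organismal_process	multiorganism_process
COMT	5	1	0	0	1	1	1	1
IL-6	4	1	1	1	1	1	1	1
SCN9A	4	1	0	0	1	1	0	0
TNF	4	1	1	1	1	1	1	1
ADRB2	3	1	0	0	1	0	1	0
ESR1	3	1	0	1	0	0	1	1
IL-10	3	1	1	1	1	1	1	1
IL-1RN	3	1	1	0	1	1	1	1
TGFB1	3	1	1	1	1	0	1	1
CRHBP	2	1	0	0	1	1	1	1
DRD4	2	1	0	0	1	1	1	1
GCH1	2	1	1	1	0	1	0	1
GSTM1	2	1	0	0	0	0	0	0
HLA-B	2	1	1	0	0	0	1	1
IL-1B	2	1	1	1	1	0	1	1
IL-4	2	1	1	1	1	0	1	1
IL-4R	2	1	1	0	1	0	1	1
P2RX7	2	1	1	1	1	1	1	1
SCN5A	2	1	0	0	1	1	1	0
SOD2	2	1	1	1	0	1	0	1
TPH2	2	1	0	0	0	0	0	0
TRPV1	2	1	0	0	1	1	0	0
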