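# Symbols shared between the 22 most consistently implicated persisting-pain
# genes and an external pain-relevant gene list.
ADRB2
COMT
ESR1
GCH1
IL-10
IL-1B
IL-4
IL-6
P2RX7
SCN9A
SOD2
TNF
TRPV1
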