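codon_third	anticodon_first	s	pairing_class	inosine
U	A	0.0	watson_crick	0
U	G	0.41	wobble	0
C	G	0.0	watson_crick	0
C	A	0.28	wobble	1
A	U	0.0	watson_crick	0
A	A	0.9999	wobble	1
G	C	0.0	watson_crick	0
G	U	0.68	wobble	0
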