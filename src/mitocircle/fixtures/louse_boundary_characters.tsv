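# Shared derived gene boundaries (characters A-K) of the ten-louse study set,
# with the taxa in which each junction is observed.  E counts the
# one-tRNA-interrupted variants (trnF-trnX-nad6) together with strict trnF-nad6.
# K's leucine tRNA is encoded as trnL2 (the isoacceptor is not printed).
# label	gene1	gene2	taxa_present
A	trnY	cox2	Heterodoxus,Bothriometopus,Ibidoecus,Pediculus
B	rrnS	rrnL	Heterodoxus,Quadraceps,Philopterus
C	trnI	cox1	Ibidoecus,Anaticola,Coloceras,Campanulotes,Philopterus,Damalinia
D	trnN	trnE	Coloceras,Campanulotes,Pediculus
E	trnF	nad6	Ibidoecus,Anaticola,Bothriometopus,Coloceras,Campanulotes,Pediculus
F	rrnL	trnW	Coloceras,Campanulotes,Quadraceps,Philopterus
G	trnA	trnG	Ibidoecus,Coloceras,Campanulotes
H	trnM	rrnS	Coloceras,Campanulotes,Quadraceps,Philopterus
I	trnK	nad4	Anaticola,Bothriometopus,Pediculus
J	trnS2	trnW	Ibidoecus,Bothriometopus,Pediculus
K	trnL2	cob	Ibidoecus,Bothriometopus
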