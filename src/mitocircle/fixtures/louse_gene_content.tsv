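# Genes sequenced per taxon (synthetic reconstruction: the printed gene
# inventories of the partial genomes are incomplete, so the unlisted slots
# were filled to respect every stated boundary and unknown-state count).
# ALL = complete 37-gene complement (on one chromosome or across minicircles).
# taxon	genes
Heterodoxus	ALL
Bothriometopus	ALL
Ibidoecus	ALL
Coloceras	ALL
Campanulotes	ALL
Pediculus	ALL
Anaticola	trnI,cox1,trnK,nad4,trnF,trnG,nad6,rrnS,rrnL,trnA,trnW,trnS2,trnN,trnE,trnY,cox2
Quadraceps	trnM,rrnS,rrnL,trnW,cob,trnL2
Philopterus	trnI,cox1,trnM,rrnS,rrnL,trnW
Damalinia	cox1,trnI,rrnL,trnP,rrnS,trnT
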