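# Synthetic stand-in for the most-rearranged complete genome of the study set
# (the deposited arrangement is not reproducible from text alone).  Constructed
# to satisfy every documented constraint: linearised on trnI-cox1, carries the
# shared derived boundaries A (trnY-cox2), C (trnI-cox1), E (trnF-nad6),
# G (trnA-trnG), J (trnS2-trnW) and K (trnL2-cob), shares no boundary with the
# ancestral insect arrangement, and lacks B, D, F, H and I.
Ibidoecus_synthetic	trnI,cox1,trnL1,cox3,rrnL,trnV,nad2,trnT,nad4,trnY,cox2,atp8,nad3,trnS1,trnM,trnR,rrnS,trnN,trnP,trnH,nad1,trnC,trnQ,trnE,nad5,trnS2,trnW,trnD,trnA,trnG,trnF,nad6,trnK,atp6,trnL2,cob,nad4L
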