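species,clade
sp09,north
sp07,north
sp22,north
sp14,north
sp02,north
sp03,north
sp19,north
sp12,north
sp08,north
sp20,north
sp18,north
sp11,north
sp04,north
sp26,north
sp15,north
sp01,north
sp05,north
sp13,south
sp24,south
sp16,south
sp10,south
sp25,south
sp17,south
sp21,south
sp23,south
sp06,south
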