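compound	S_thermophilus	L_bulgaricus
Amino acids	consumes	provides
Carbon dioxide	provides	consumes
Fatty acids	provides	consumes
Folic acid	provides	consumes
Formic acid	provides	consumes
Ornithine	provides	consumes
Peptides	consumes	provides
Putrescine	consumes	provides
Pyruvatic acid	provides	consumes
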