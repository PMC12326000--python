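residue,area
D57,BA1
E97,BA1
K99,BA1
D114,BA1
K115,BA1
E116,BA1
G183,BA1
D42,BA2
D140,BA2
E164,BA2
D169,BA2
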