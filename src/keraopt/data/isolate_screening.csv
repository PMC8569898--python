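isolate,keratinase,amino_acids
ZW-5,113.8,444.3
ZW-6,34.2,236.9
ZW-9,19.4,103.9
ZW-13,6.2,89.4
ZW-17,5,9
ZW-20,5,9
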