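>cne_reference_synthetic 156 bp synthetic alphabaculovirus-style CNE (constructed stand-in, not from any deposited genome)
CAAAACTTTGATTATAACAATCGCTACTTCTAATTATCTGACACGATTGTTATAAGTTAA
GCAGTAGACGTACTGATTAGAAATGTCAATACGTCTACTGTTGGTTATTAGCGGATGTTA
ACGACTTTTTAAGCCAAAACATCCGCTAATATTTGA
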