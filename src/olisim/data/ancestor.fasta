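>Oli_ancestor 107-nt founding hairpin
AAGCAGTGGGAGACCGAGTTATCCAAGTATAGAGCCGACCCCAACAACAGCAGGCTGCTC
CCATTAACCCCAGGCTCAGATCTGGGTCTATACTTCCTTCGGTCTCC
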