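>fwd qPCR primer, binds the self-primed extension
AAGCAGTGGGAGACCGAAGG
>rev qPCR primer, binds the 5p end region (2 designed mismatches vs ancestor)
AAGCAGTGGGAGACGTAGTTATCCA
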