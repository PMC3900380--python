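H1
H2BUb
H3K18ac
H3K23ac
H3K27ac
H3K27me2
H3K27me3
H3K36me1
H3K36me3
H3K4me1
H3K4me3
H3K79me1
H3K79me2
H3K9acS10P
H3K9ac
H3K9me1
H3K9me2
H3K9me3
H4K16ac
H4K20me
H4
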