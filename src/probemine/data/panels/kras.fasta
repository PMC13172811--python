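>Kras G12A inv k
TCTTGCCTACGCCACG
>Kras G12C inv k
TCTTGCCTACGCCACA
>Kras G12D inv k
CTCTTGCCTACGCCAT
>Kras G12R inv k
TCTTGCCTACGCCACG
>Kras G12S inv k
TCTTGCCTACGCCACT
>Kras G12V inv k
CTCTTGCCTACGCCAA
>Kras G13D inv k
GCACTCTTGCCTACGT
>Kras A1 inv k
GCCTGCTGAAAATGACTGA
>Kras B1 inv k
CCTTGGGTTTCAAGTTATATG
>Kras B2 inv k
CCCTGACATACTCCCAAGGA
>Kras-A
CATCTCTTGCCCTCTCAAAG
>Kras-B
CTCTTGCCCTCTCAAAGTGC
>Kras-C
GCCCTCTCAAAGTGCTGGT
>Kras-D
TGGCATCTCTTGCC
>Kras-E
CATCTCTTGCCCTCTCAAAG
>Kras-F
GCCCTCTCAAAGTGCTGGT
>Kras-G
CTCTCAAAGTGCTG
>Kras-H
CAAAGTGCTGGTAC
>Kras-I
GTGCTGGTACTACA
>Beta-actin-F
AGAGATGGCCACGGCTGCTT
>Beta-actin-R
ATTTGCGGTGGACGATGGAG
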