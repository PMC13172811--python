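>BECO5
GGCATCAAACAGCTCCAGGCAAG
>BECO3
AGCAAAGCCCTTTCTAAGCCCTGTCT
>BE-ANCH
TCCTGGCTGTGGAAAGATACCTA
>B-SPEC
GTCCCCTCGGGGCTGGGAGG
>E-SPEC
GTCTCAGTCCCTTGAGACTGCTG
>F-SPEC
AACAGCTCTACCAGCTCTTTGCAAA
>C-SPEC
AGACCCCAATACTGCACAAGACTT
>5'E
CAGGAAAGGAATGAAAAGGATTTGTTA
>3'E
ATAACCCTATCTGTCCACCCC
>5'A
GANAACATGACCTGGCTGC
>3'A
TCTATAACCCTATCTGTCCAGCCA
>5'G
ACAATTACACATACCACATATACAGCC
>3'G
TCTATAACCCTATCTGTCCAGTT
>5'D
ACCACTAATGTGCCCTGGAACT
>3'D
AGGAGGGTCTGAAATGACAGA
>SK29
ACTAGGGAACCCACTGCT
>SK30
GGTCTGAGGGATCTCTA
>SK31
ACCAGAGTCACACAACAGACGGGCACACACTACT
>SK38
ATAATCCACCTATCCCAGTAGGAGAAAT
>SK39
TTTGGTCCTTGTCTTATGTCCAGAATGC
>SK19
ATCCTGGGATTAAATAAAATAGTAAGAATGTATAGCCCTAC
>SK68
AGCAGCAGGAAGCACTATGG
>SK69
CCAGACTGTGAGTTGCAACAG
>SK70
ACGGTACAGGCCAGACAATTATTGTCTGGTATAGT
>CO1
ACAATTATTGTCTGGTATAG
>CO2
AGGTATCTTTCCACAGCCAG
>CO3
TGAGTTGCAACAGATGCTGTTGCGCCTCAATAGCCCTCAG
>JA167
TATCYTTTGAGCCAATTCCYATACA
>JA168
ACAATGYACACATGGAATTARGCCA
>JA169
AGAAAAATTCYCCTCYACAATTAAA
>JA170
GTGATGTATTRCARTAGAAAAATTC
>Beta-actin-F
AGAGATGGCCACGGCTGCTT
>Beta-actin-R
ATTTGCGGTGGACGATGGAG
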