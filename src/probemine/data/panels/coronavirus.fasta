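>CDC-F
CCCTGTGGGTTTTACACTTAA
>CDC-p
CCGTCTGCGGTATGTGGAAAGGTTATGG
>CDC-R
ACGATTGTGCATCAGCTGA
>CDC-N-F
GGGGAACTTCTCCTGCTAGAAT
>CDC-N-P
TTGCTGCTGCTTGACAGATT
>CDC-N-R
CAGACATTTTGCTCTCAAGCTG
>HKU-ORF1b-F
TGGGGYTTTACRGGTAACCT
>HKU-ORF1b-P
TAGTTGTGATGCWATCATGACTAG
>HKU-ORF1b-R
AACRCGCTTAACAAAGCACTC
>HKU-N-F
TAATCAGACAAGGAACTGATTA
>HKU-N-P
GCAAATTGTGCAATTTGCGG
>HKU-N-R
CGAAGGTGTGACTTCCATG
>USA-F-1
GACCCCAAAATCAGCGAAAT
>USA-P-1
ACCCCGCATTACGTTTGGTGGACC
>USA-R-1
TCTGGTTACTGCCAGTTGAATCTG
>USA-F-2
TTACAAACATTGGCCGCAAA
>USA-P-2
ACAATTTGCCCCCAGCGCTTCAG
>USA-R-2
GCGCGACATTCCGAAGAA
>USA-F-3
GGGAGCCTTGAATACACCAAAA
>USA-P-3
AYCACATTGGCACCCGCAATCCTG
>USA-R-3
TGTAGCACGATTGCAGCATTG
>GRT-F
GTGARATGGTCATGTGTGGCGG
>GRT-P1
CAGGTGGAACCTCATCAGGAGATGC
>GRT-P2
CCAGGTGGWACRTCATCMGGTGATGC
>GRT-R
CARATGTTAAASACACTATTAGCATA
>GRT-E-F
ACAGGTACGTTAATAGTTAATAGCGT
>GRT-E-P
ACACTAGCCATCCTTACTGCGCTTCG
>GRT-E-R
ATATTGCAGCAGTACGCACACA
>GRT-N-F
CACATTGGCACCCGCAATC
>GRT-N-P
ACTTCCTCAAGGAACAACATTGCCA
>GRT-N-R
GAGGAACGAGAAGAGGCTTG
>Paris-IP2-F
ATGAGCTTAGTCCTGTTG
>Paris-IP2-R
CTCCCTTTGTTGTGTTGT
>Paris-IP2-P
AGATGTCTTGTGCTGCCGGTA
>Paris-IP4-F
GGTAACTGGTATGATTTCG
>Paris-IP4-R
CTGGTCAAGGTTAATATAGG
>Paris-IP4-P
TCATACAAACCACGCCAGG
>Jap-F
AAATTTTGGGGACCAGGAAC
>Jap-R
TGGCAGCTGTGTAGGTCAAC
>Jap-P
ATGTCGCGCATTGGCATGGA
>Thailand-F
CGTTTGGTGGACCCTCAGAT
>Thailand-R
CCCCACTGCGTTCTCCATT
>Thailand-P
CAACTGGCAGTAACCA
>Pan-SARS-ORF1ab-F
GGAAAGGTTATGGCTGTAGTTGTG
>Pan-SARS-ORF1ab-R
CCGCACGGTGTAAGACGG
>Pan-SARS-ORF1ab-P
AACGGGTTTGCGGTGTAAGTGCAG
>Pan-SARS-E-F
ACACTAGCCATCCTTACTG
>Pan-SARS-E-R
CACGTTAACAATATTGCAGC
>Pan-SARS-E-P
CGCTTCGATTGTGTGCGTACT
>Pan-SARS-N-F
ACATTGGCACCCGCAATCC
>Pan-SARS-N-R
GCTTGACTGCCGCCTCTGCT
>Pan-SARS-N-P
CGTGCTACAACTTCCTCAAGGAACA
>BCoV_Forward
CTAGTAACCAGGCTGATGTCAATACC
>BCoV_Reverse
GGCGGAAACCTAGTCGGAATA
>AC01-F
TTTGTGTCTACTYYTCTCAACTA
>AC01-R
GCATTMACCCAACAATTATTRT
>AC02-F
TTTAATGTTGTWGGKCCICG
>AC02-R
GCATAACAAGCRCARCGRTA
>AC03-F
GGTGGTRAYAATGTTTATTGYTA
>AC03-R
AGRCCAAAATCACTRTGYTTA
>AC04-F
TAYCGYTGYGCTTGTTATGC
>AC04-R
GGWACACCATCWATAAAMAC
>AC05-F
CTGGTARYGGTCARGCTAT
>AC05-R
CAYTTAGTRCACAACATMGG
>AC06-F
GTKTTTATWGATGGTGTWCC
>AC06-R
ACATCCATWCCYAACCAACC
>AC07-F
CCKATGTTGTGYACTAARTG
>AC07-R
CTRCCATCRTACATATCWGA
>AC08-F
GGTTGGTTRGGWATGGATGT
>AC08-R
TAAGGCRTCTTCWATRGTTTTACA
>AC09-F
TATGGTGATGTKTCWAAAACTAC
>AC09-R
TCRTAATAAGGAAGTTTAGTTGA
>AC10-F
TGTAAAACYATWGAAGAYGCCTTA
>AC10-R
AAAAATGGCTCTTCCATTGTTGGC
>Chu-RdRp-N1-F
GGKTGGGAYTAYCCKAARTG
>Chu-RdRp-N1-R
TGYTGTSWRCARAAYTCRTG
>Chu-RdRp-N2-F
GGTTGGGACTATCCTAAGTGTGA
>Chu-RdRp-N2-R
CCATCATCAGATAGAATCATCAT
>Bat-Cov-RdRp-1-F
AYAACCAAGATCTTAATGG
>Bat-Cov-RdRp-1-R
TGCTTAGAACCCAAAATCAT
>Bat-Cov-RdRp-2-F
GGTTGGGACTATCCTAAGTGTGA
>Bat-Cov-RdRp-2-R
CCATCATCAGATAGAATCATCATA
>Bat-Cov-Heli-F
CTCARGGTAGTGARTATGA
>Bat-Cov-Heli-R
AATTGTTCWCCWGGTGG
>Bat-Cov-S-1-F
WTATGTTTGYAATGGTAAY
>Bat-Cov-S-1-R
GTCWTCATCMACWGTRC
>Bat-Cov-S-2-F
GAYTDDCAGCACTTAATGC
>Bat-Cov-S-2-R
TTGAGCCAYTCAAGRTYRA
>Bat-Cov-S-3-F
CAATCTAGGTCTGCTATCG
>Bat-Cov-S-3-R
CTAGAAGACTGTGATTTGA
>FcovP
TCCATTGTTGGCTCGTCATAGCGGA
>FcovF
GATTTGATTTGGCAATGCTAGATTT
>FcovR
AACAATCACTAGATCCAGACGTTAGCT
>FPVp
CTGGGGGTGTGGGGATTTCTACG
>FPVf
CGGGGGTGGTGGTGGTT
>FPVr
GCTTGAGTTTGCTGTGATTTCC
>HNL-2111F
CARTCWACWGTGGGCAGTGG
>HANL-R1
AACCADTCWGTYCCRTCATC
>HANL-R2
GCRTCRTCWGARTGRTGDGCAA
>HHSIF
GTAAGCCCTGTCATGAGTGTAG
>HHSIQ
TTGCATGTTGCCTGAGGGCTTGA
>PAR-F1
GAAGGTATTGTCAAARNTNTGGAC
>PAR-F2
GTTGCTTCAATGGTTCARGGNGAYAA
>PAR-R
GCTGAAGTTACGGTCCCDATRTTNC
>BconPVF
TYCCWAAGGTSTCTGSAAATCA
>BconPVR
GTACGACTCACTATAGGGA
>M30F2/08
ATGAGYCTTYTAACCGAGGTCGAAACG
>M264R3/08
TGGACAAANCGTCTACGCTGCAG
>H5-918F
CCARTRGGKGCKATAAAYTC
>H5-671-647R
CTCTGGTTTAGTGTTGATGTYCCAA
>H1-HARend
AGTAGAAACAAGGGTGTTTTT
>H1-HAFA
GGGAGAATGAACTATTACTGG
>OR237969.1 CRFK_cell_DDX20_1
TACCATTGCTTTGGACTCTC
>OR237969.1 CRFK_cell_DDX20_2
CTGGCCGTTTTGGTACCTTG
>OR237969.1 CRFK_cell_DDX20_3
CCTGTGAAAAGCCACTCAGA
>OR237969.1 CRFK_cell_DDX20_4
CCTGAAGAGAGAGTGCAGGT
>OR237969.1 CRFK_cell_DDX20_5
GGACGGTTGGTACGACTGCC
>Beta-actin-F
AGAGATGGCCACGGCTGCTT
>Beta-actin-R
ATTTGCGGTGGACGATGGAG
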