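>example_query 270 bp worked-example sequence
TGAGTTTAAAAACTGGACCAGTGAAAATGAAATAATTGATAATCTTATTTTAGAAATGCA
ATTAAAAATTAATAGTACATATGATAAAATAGTTGAATGGATACCATACAATCAGTTTAT
TAACATTAACGAAATAGGAAAAGTTGGTGATAATACTGCTGTATATTCAGCAATATGGAA
AAATGGTCCACTATATTATAGAAAGAAATGGATAAGGAAATCCAATGAAAAAGTTGTATT
AAATTACTTAACATTAGATATTAAGGAATT
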