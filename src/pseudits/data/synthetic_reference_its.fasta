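>synthetic_reference_its
GCAATTGGGTTATAGATGCCAAGGGCTTGGGCAGGCCTTCGCGCCTCGATGCTACACGCACAAGCGATCA
GTCTCCGTTCGCGGCGGTAGTTATTTATTTCCTTCGCTAGGAGAGGTATACCTGCCTCACGGTGCCTGTC
GGTACTATCTACAGCGTATACCCTGCCTTGCTCATTGTTGTCAGGACTGGAGGATGAGTGCAGAGGTACG
ACAGACTCTGTAAATGCAGCGAATTGCAGAATCCTGGTATCCTGCCTAGGGCGCCCGACAGTAGTTTCTT
GGTCTGCGGATTTGAACGCATGAGGTGTTCACGCGAGCATGCTAGCAGCCTAGAATGGCGCGATGAAGAA
CGTAGCGTCCTGCCAAGATACCCGGGACGCAATATTCCTGTGGTTAGACCCTAACTCTAGTGTGTTGTGC
GCGAGGGGAGCGGGGGCCCGGATGGTCCCAGTGCGGTCATTAAGGGAAGTCAGAAGTCCCCGGCGGGCGG
CCGGGCGTCTATTCACATTTGGTGCTCGGACGAACGGCGCTGTCAACGAGTCGGGACGGTCCCCGCTCGG
GTAAAAGATACCCCCCTCCGGGAGGGGAACTCTCGCGCTCAGGGGGAGAAC
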