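>qPCR_sgRNA_fw type=primer scaffold-specific forward qPCR primer
TGCTGGAAACAGCATAGCAAGTTT
>qPCR_sgRNA_rv type=primer scaffold-specific reverse qPCR primer
GACTCGGTGCCACTTTTTCAAGTT
>qPCR_HEK2std type=standard_oligo cDNA-sense standard for HEK2 sgRNA
AAAAAAAGCACCGACTCGGTGCCACTTTTTCAAGTTGATAACGGACTAGCCTTATTTAAACTTGCTATGCTGTTTCCAGCATAGCTCTTAAACGCAGTCTATGCTTTGTGTTC
>qPCR_HEK3std type=standard_oligo cDNA-sense standard for HEK3 sgRNA
AAAAAAAGCACCGACTCGGTGCCACTTTTTCAAGTTGATAACGGACTAGCCTTATTTAAACTTGCTATGCTGTTTCCAGCATAGCTCTTAAACTCACGTGCTCAGTCTGGGCC
>qPCR_CFex11std type=standard_oligo cDNA-sense standard for CFex11 sgRNA
AAAAAAAGCACCGACTCGGTGCCACTTTTTCAAGTTGATAACGGACTAGCCTTATTTAAACTTGCTATGCTGTTTCCAGCATAGCTCTTAAACCTTCTAGTTGGCATGCTTTG
>spacer_AAVS1 type=spacer
GGGGCCACTAGGGACAGGAT
>spacer_HEK2 type=spacer
GAACACAAAGCATAGACTGC
>spacer_HEK3 type=spacer
GGCCCAGACTGAGCACGTGA
>spacer_CFex11 type=spacer
CAAAGCATGCCAACTAGAAG
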