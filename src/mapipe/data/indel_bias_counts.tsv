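motif_class	group	insertions	deletions
A/T	homopolymer	151	1983
C/G	homopolymer	10	28
AT/TA	dinucleotide	71	42
GT/CA	dinucleotide	6	11
GA/CT	dinucleotide	1	1
AAT/TTA	trinucleotide	1	1
AAC/TTG	trinucleotide	1	3
ATT/TAA	trinucleotide	3	0
ACG/TGC	trinucleotide	0	1
ATG/TAC	trinucleotide	3	1
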