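# Conserved sequence block consensus set for the grouper (Epinephelidae)
# mitochondrial control region.  Blocks F..A span the central conserved
# domain; blocks 1..3 lie downstream of it.  Editable: rows may be added
# or replaced for other taxa.
# block_id	consensus	source
F	GCACAGTAAGAACCTACCAA	epinephelid_consensus
E	GACAATAATTGTGGGGGT	epinephelid_consensus
D	TATTCCTGGCATTTGGTTCCTACTTCAGGGCCA	epinephelid_consensus
C	CTTTCATTGACGCTTGCATAAGTTAATG	epinephelid_consensus
B	CATTCGACTCGTTACCCA	epinephelid_consensus
A	TCCAGAGGGTAGGGGGTT	epinephelid_consensus
1	CATAACTGATTTCAAGAACATAA	epinephelid_consensus
2	TAAACCCCCCTACCCCCC	epinephelid_consensus
3	TGTAAACCCCCCGGAAACA	epinephelid_consensus
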