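# Gene-name synonym table: alias -> canonical symbol.
# GenBank feature naming varies across submitters; extend as needed.
# alias	canonical
COX1	COI
COXI	COI
CO1	COI
COX2	COII
COXII	COII
CO2	COII
COX3	COIII
COXIII	COIII
CO3	COIII
ATPASE8	ATP8
ATPASE 8	ATP8
ATP SYNTHASE 8	ATP8
ATPASE6	ATP6
ATPASE 6	ATP6
ATP SYNTHASE 6	ATP6
CYT B	CYTB
CYTOCHROME B	CYTB
COB	CYTB
CYB	CYTB
NAD1	ND1
NAD2	ND2
NAD3	ND3
NAD4	ND4
NAD4L	ND4L
NAD5	ND5
NAD6	ND6
12S RIBOSOMAL RNA	12S rRNA
12S-RRNA	12S rRNA
RRNS	12S rRNA
S-RRNA	12S rRNA
SMALL SUBUNIT RIBOSOMAL RNA	12S rRNA
16S RIBOSOMAL RNA	16S rRNA
16S-RRNA	16S rRNA
RRNL	16S rRNA
L-RRNA	16S rRNA
LARGE SUBUNIT RIBOSOMAL RNA	16S rRNA
D-LOOP	CR
D LOOP	CR
CONTROL REGION	CR
OL	OL
O_L	OL
L-STRAND ORIGIN	OL
ORIGIN OF L-STRAND REPLICATION	OL
TRNA-LEU1	tRNA-Leu(UUR)
TRNA-LEU (UUR)	tRNA-Leu(UUR)
TRNA-LEU2	tRNA-Leu(CUN)
TRNA-LEU (CUN)	tRNA-Leu(CUN)
TRNA-SER1	tRNA-Ser(UCN)
TRNA-SER (UCN)	tRNA-Ser(UCN)
TRNA-SER2	tRNA-Ser(AGY)
TRNA-SER (AGY)	tRNA-Ser(AGY)
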