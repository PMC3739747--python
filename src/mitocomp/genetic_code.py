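"""Vertebrate mitochondrial genetic code helpers.

All translation and stop-codon logic in the package uses NCBI
translation table 2, in which AGA/AGG are stops and TGA codes for Trp —
the standard code would misclassify both.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[2]

BASES = "ACGT"
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)  # TAA TAG AGA AGG
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
START_CODONS: frozenset[str] = frozenset(_TABLE.start_codons)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def codons_of(cds: str) -> list[str]:
    """Full codons of a CDS read in frame 0; a trailing incomplete codon
    (length mod 3 leftovers) is dropped."""
    return [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]


def translate_cds(cds: str) -> str:
    """Translate a CDS, dropping any incomplete terminal codon and a
    terminal stop; internal stops translate to '*'."""
    aas = [translate_codon(c) if "N" not in c else "X" for c in codons_of(cds)]
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def internal_stops(cds: str) -> list[int]:
    """Codon indices (0-based) of internal stop codons in frame 0."""
    cods = codons_of(cds)
    return [i for i, c in enumerate(cods[:-1]) if "N" not in c and is_stop(c)]
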