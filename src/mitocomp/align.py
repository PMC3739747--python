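"""Alignment helpers: pairwise global identity and multiple alignment.

Pairwise identity uses Biopython's global aligner.  Multiple alignment
delegates to MAFFT when sequences differ in length; equal-length inputs
(the common case for substitution-only comparisons) pass through
unchanged.  CDS alignment is codon-aware: sequences are aligned as
amino acids and gaps back-threaded in multiples of three.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from Bio import Align

from .genetic_code import translate_cds

__all__ = ["pairwise_identity", "multiple_align", "codon_aware_align"]

_NT_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=-1,
    open_gap_score=-4, extend_gap_score=-1)
_AA_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=-1,
    open_gap_score=-4, extend_gap_score=-1)


def pairwise_identity(a: str, b: str, alphabet: str = "NT") -> float:
    """Percent identity of the best global alignment of two sequences.

    NT scoring: match +1 / mismatch -1 / gap open -4 / gap extend -1;
    AA scoring: uniform +1/-1 with the same gap penalties.  Identity is
    identical columns over all alignment columns, gap columns included
    (which penalizes indel-rich regions consistently).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aligner = _NT_ALIGNER if alphabet.upper() == "NT" else _AA_ALIGNER
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns


def multiple_align(seqs: dict[str, str]) -> dict[str, str]:
    """Multiple-align sequences; equal-length inputs are returned as-is,
    otherwise MAFFT (``--auto``) produces the alignment."""
    if len({len(s) for s in seqs.values()}) <= 1:
        return dict(seqs)
    if shutil.which("mafft") is None:
        raise RuntimeError("sequences differ in length and MAFFT is not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        with open(inp, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", str(inp)],
            capture_output=True, text=True, check=True)
    out: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name:
            out[name] += line.strip().upper()
    return out


def codon_aware_align(cds_seqs: dict[str, str]) -> dict[str, str]:
    """Align coding sequences with gaps constrained to codon boundaries.

    Sequences are translated (vertebrate mitochondrial code), aligned as
    amino acids, and the gap pattern back-threaded onto the nucleotide
    sequences in multiples of three.  Incomplete terminal codons are
    trimmed first.
    """
    trimmed = {k: s[: len(s) - len(s) % 3] for k, s in cds_seqs.items()}
    aa = {k: translate_cds(s) for k, s in trimmed.items()}
    aa_aln = multiple_align(aa)
    out: dict[str, str] = {}
    for name, aligned_aa in aa_aln.items():
        nt = trimmed[name]
        codons, pos, parts = len(nt) // 3, 0, []
        for ch in aligned_aa:
            if ch == "-":
                parts.append("---")
            else:
                parts.append(nt[3 * pos:3 * pos + 3])
                pos += 1
        # a trimmed terminal stop is not translated; keep tail codons
        while pos < codons:
            parts.append(nt[3 * pos:3 * pos + 3])
            pos += 1
        out[name] = "".join(parts)
    if len({len(s) for s in out.values()}) > 1:
        length = max(len(s) for s in out.values())
        out = {k: s.ljust(length, "-") for k, s in out.items()}
    return out
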