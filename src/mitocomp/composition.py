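"""Composition-level statistics: base composition, AT/GC skew,
codon-position composition per strand class, and the start/stop-codon
catalogue with incomplete-stop detection.

Skews follow the strand-asymmetry convention AT-skew = (A-T)/(A+T) and
GC-skew = (G-C)/(G+C), computed from the same counts as the reported
percentages.  N positions are excluded from all denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .genetic_code import codons_of, internal_stops, is_stop
from .model import Mitogenome

__all__ = [
    "CompositionSummary",
    "CodonUsageProfile",
    "StartStopRecord",
    "base_composition",
    "skew_from_percentages",
    "codon_position_composition",
    "start_stop_catalogue",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Half-up decimal rounding for report output (banker's rounding of
    the builtin would round 0.045 -> 0.04).  Binary float noise is
    absorbed at ndigits+6 places first so that a value that is exactly
    x.xx5 in decimal arithmetic rounds up as intended."""
    d = Decimal(repr(x)).quantize(Decimal(1).scaleb(-(ndigits + 6)))
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass
class CompositionSummary:
    """Base counts/percentages and strand-asymmetry skews of one sequence."""

    counts: dict[str, int]
    percent: dict[str, float]  # % of non-N positions
    at_skew: float
    gc_skew: float
    n_count: int = 0

    def rounded(self) -> dict[str, float]:
        """Report-precision values: composition at 1 d.p., skews at 2 d.p."""
        out = {b: round_half_up(self.percent[b], 1) for b in "ATGC"}
        out["at_skew"] = round_half_up(self.at_skew, 2)
        out["gc_skew"] = round_half_up(self.gc_skew, 2)
        return out


def base_composition(seq: str) -> CompositionSummary:
    """Composition and skews of a DNA string; N excluded from denominators."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    n_count = seq.count("N")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("composition undefined: sequence has no unambiguous bases")
    a, t, g, c = counts["A"], counts["T"], counts["G"], counts["C"]
    return CompositionSummary(
        counts=counts,
        percent={b: 100.0 * counts[b] / total for b in "ACGT"},
        at_skew=(a - t) / (a + t) if a + t else 0.0,
        gc_skew=(g - c) / (g + c) if g + c else 0.0,
        n_count=n_count,
    )


def skew_from_percentages(a: float, t: float, g: float, c: float) -> tuple[float, float]:
    """AT- and GC-skew recomputed directly from printed base percentages."""
    return (a - t) / (a + t), (g - c) / (g + c)


@dataclass
class CodonUsageProfile:
    """Pooled per-codon-position nucleotide percentages for one strand class.

    ``position_percent[p][base]`` gives the percentage of ``base`` among
    all full codons' position-``p`` nucleotides (p in 1..3).  The heavy
    strand pools the 12 H-strand CDS; the light-strand class is ND6
    alone and is never pooled with it, because the third-position
    anti-G/anti-C bias is strand-specific.
    """

    strand_class: str  # "H" | "L"
    position_counts: dict[int, dict[str, int]]
    position_percent: dict[int, dict[str, float]] = field(init=False)
    n_codons: int = 0

    def __post_init__(self) -> None:
        self.position_percent = {}
        for p, counts in self.position_counts.items():
            total = sum(counts.values())
            self.position_percent[p] = {
                b: (100.0 * counts[b] / total if total else 0.0) for b in "ATGC"}

    def at_percent(self, position: int) -> float:
        pp = self.position_percent[position]
        return pp["A"] + pp["T"]


def codon_position_composition(cds_seqs: dict[str, str] | list[str],
                               strand_class: str = "H") -> CodonUsageProfile:
    """Pooled nucleotide composition at each codon position.

    Incomplete terminal codons (length mod 3 leftovers) are excluded.
    Codons containing N contribute only their unambiguous positions.
    Internal stop codons trigger a validation warning naming the gene
    and codon index but still count.
    """
    if isinstance(cds_seqs, list):
        cds_seqs = {f"cds_{i}": s for i, s in enumerate(cds_seqs)}
    counts = {p: {b: 0 for b in "ACGT"} for p in (1, 2, 3)}
    n_codons = 0
    for name, seq in cds_seqs.items():
        seq = seq.upper()
        if len(seq) < 3:
            raise ValueError(f"{name}: CDS shorter than one codon")
        bad = internal_stops(seq)
        if bad:
            warnings.warn(
                f"{name}: internal stop codon(s) at codon index {bad} "
                "under the vertebrate mitochondrial code")
        for codon in codons_of(seq):
            n_codons += 1
            for p, base in enumerate(codon, start=1):
                if base in counts[p]:
                    counts[p][base] += 1
    return CodonUsageProfile(strand_class=strand_class, position_counts=counts,
                             n_codons=n_codons)


@dataclass
class StartStopRecord:
    gene: str
    start_codon: str
    stop_codon: str  # literal terminal residues: TAA/TAG/TA/T
    incomplete_stop: bool


def start_stop_catalogue(genome: Mitogenome,
                         trna_gap_bp: int = 2) -> list[StartStopRecord]:
    """Start and stop codons of every CDS in a genome.

    The stop is recorded as the literal terminal residues of the
    annotated span: the final full codon when length is a multiple of 3,
    otherwise the 1- or 2-base leftover.  A terminal ``T``/``TA``
    immediately (within ``trna_gap_bp``) upstream of a same-strand tRNA
    is flagged ``incomplete_stop`` — such messages are completed to TAA
    by post-transcriptional polyadenylation.
    """
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    records = []
    for i, f in enumerate(feats):
        if f.ftype != "CDS":
            continue
        seq = genome.feature_sequence(f)
        rem = len(seq) % 3
        stop = seq[-3:] if rem == 0 else seq[-rem:]
        incomplete = False
        if stop in ("T", "TA"):
            nxt = feats[(i + 1) % len(feats)] if f.strand == "H" else feats[i - 1]
            gap = (nxt.start - f.end) if f.strand == "H" else (f.start - nxt.end)
            if f.wraps_origin or nxt.wraps_origin:
                gap = gap % genome.length_bp
            if nxt.ftype == "tRNA" and 0 <= gap <= trna_gap_bp:
                incomplete = True
        records.append(StartStopRecord(
            gene=f.name, start_codon=seq[:3], stop_codon=stop,
            incomplete_stop=incomplete))
    return records
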