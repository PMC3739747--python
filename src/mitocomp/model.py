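"""Core data model for circular mitochondrial genomes.

Coordinates are 0-based half-open on the heavy strand throughout the
package; report output converts to 1-based inclusive for display.  A
feature that crosses the circular origin keeps its true length and is
marked with ``wraps_origin`` rather than being split in two.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GeneFeature",
    "Mitogenome",
    "reverse_complement",
    "CANONICAL_GENE_ORDER",
    "CANONICAL_TRNAS",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Canonical vertebrate mitochondrial gene order on the heavy strand,
#: starting from tRNA-Phe, with strand assignments.  ND6 and eight tRNAs
#: (Gln, Ala, Asn, Cys, Tyr, Ser-UCN, Glu, Pro) are light-strand encoded.
CANONICAL_GENE_ORDER: tuple[tuple[str, str, str], ...] = (
    ("tRNA-Phe", "tRNA", "H"),
    ("12S rRNA", "rRNA", "H"),
    ("tRNA-Val", "tRNA", "H"),
    ("16S rRNA", "rRNA", "H"),
    ("tRNA-Leu(UUR)", "tRNA", "H"),
    ("ND1", "CDS", "H"),
    ("tRNA-Ile", "tRNA", "H"),
    ("tRNA-Gln", "tRNA", "L"),
    ("tRNA-Met", "tRNA", "H"),
    ("ND2", "CDS", "H"),
    ("tRNA-Trp", "tRNA", "H"),
    ("tRNA-Ala", "tRNA", "L"),
    ("tRNA-Asn", "tRNA", "L"),
    ("OL", "noncoding", "H"),
    ("tRNA-Cys", "tRNA", "L"),
    ("tRNA-Tyr", "tRNA", "L"),
    ("COI", "CDS", "H"),
    ("tRNA-Ser(UCN)", "tRNA", "L"),
    ("tRNA-Asp", "tRNA", "H"),
    ("COII", "CDS", "H"),
    ("tRNA-Lys", "tRNA", "H"),
    ("ATP8", "CDS", "H"),
    ("ATP6", "CDS", "H"),
    ("COIII", "CDS", "H"),
    ("tRNA-Gly", "tRNA", "H"),
    ("ND3", "CDS", "H"),
    ("tRNA-Arg", "tRNA", "H"),
    ("ND4L", "CDS", "H"),
    ("ND4", "CDS", "H"),
    ("tRNA-His", "tRNA", "H"),
    ("tRNA-Ser(AGY)", "tRNA", "H"),
    ("tRNA-Leu(CUN)", "tRNA", "H"),
    ("ND5", "CDS", "H"),
    ("ND6", "CDS", "L"),
    ("tRNA-Glu", "tRNA", "L"),
    ("CYTB", "CDS", "H"),
    ("tRNA-Thr", "tRNA", "H"),
    ("tRNA-Pro", "tRNA", "L"),
    ("CR", "noncoding", "H"),
)

#: The canonical 22-gene tRNA complement of the vertebrate mitogenome.
CANONICAL_TRNAS: tuple[str, ...] = tuple(
    name for name, ftype, _ in CANONICAL_GENE_ORDER if ftype == "tRNA"
)


def reverse_complement(seq: str) -> str:
    """Return the reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """One annotated gene or region on a circular mitogenome.

    ``start``/``end`` are 0-based half-open heavy-strand coordinates.
    ``wraps_origin`` marks a feature crossing the circular origin; its
    ``end`` is then numerically smaller than ``start`` and the feature
    occupies ``[start, L) + [0, end)``.
    """

    name: str
    ftype: str  # CDS | tRNA | rRNA | noncoding
    start: int
    end: int
    strand: str = "H"  # H | L
    anticodon: str = ""  # 3-letter RNA string for tRNAs, "" if n/a
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.ftype not in ("CDS", "tRNA", "rRNA", "noncoding"):
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if not self.wraps_origin and self.end <= self.start:
            raise ValueError(
                f"{self.name}: end ({self.end}) must exceed start ({self.start}) "
                "unless the feature wraps the origin"
            )

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.end
        return self.end - self.start


@dataclass
class Mitogenome:
    """A circular mitochondrial genome with an ordered feature table."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"{self.id}: sequence contains characters outside A/C/G/T/N: "
                f"{sorted(bad)} (IUPAC ambiguity codes other than N are rejected)"
            )
        self.sequence = self.sequence.upper()

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def sort_features(self) -> None:
        """Sort features by heavy-strand start position (in place)."""
        self.features.sort(key=lambda f: (f.start, f.end))

    # -- feature lookup -------------------------------------------------

    def get_features(self, name: str) -> list[GeneFeature]:
        return [f for f in self.features if f.name == name]

    def get_feature(self, name: str) -> GeneFeature:
        hits = self.get_features(name)
        if not hits:
            raise KeyError(f"{self.id}: no feature named {name!r}")
        if len(hits) > 1:
            raise KeyError(
                f"{self.id}: feature name {name!r} is duplicated "
                f"({len(hits)} copies); use get_features() to disambiguate"
            )
        return hits[0]

    # -- sequence extraction --------------------------------------------

    def heavy_strand_slice(self, feature: GeneFeature) -> str:
        """The genomic (heavy-strand) slice under a feature, linearized."""
        if feature.wraps_origin:
            return self.sequence[feature.start:] + self.sequence[: feature.end]
        return self.sequence[feature.start:feature.end]

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Feature sequence in coding sense (5'->3').

        Light-strand features are returned reverse-complemented so the
        result reads in the direction the gene is transcribed.
        """
        s = self.heavy_strand_slice(feature)
        return reverse_complement(s) if feature.strand == "L" else s

    def extract_gene(self, name: str) -> str:
        """Coding-sense sequence of a uniquely named feature."""
        return self.feature_sequence(self.get_feature(name))

    def copy(self) -> "Mitogenome":
        return Mitogenome(
            id=self.id,
            sequence=self.sequence,
            features=[replace(f) for f in self.features],
        )


def intergenic_table(genome: Mitogenome) -> list[tuple[str, str, int]]:
    """Spacer/overlap lengths between consecutive features around the circle.

    Returns ``(upstream_name, downstream_name, spacer_bp)`` for every
    adjacent pair in heavy-strand order, including the wrap-around pair.
    Negative values are overlapping nucleotides.
    """
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    if len(feats) < 2:
        return []
    out: list[tuple[str, str, int]] = []
    n = genome.length_bp
    for cur, nxt in zip(feats, feats[1:] + feats[:1]):
        cur_end = cur.end if not cur.wraps_origin else cur.end + n
        nxt_start = nxt.start
        if nxt is feats[0]:  # wrap-around pair
            nxt_start += n
        spacer = nxt_start - cur_end
        out.append((cur.name, nxt.name, spacer))
    return out
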