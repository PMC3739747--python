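"""Structural annotation of mitogenome non-coding elements.

Covers the control region (tandem ETAS repeats carrying TAS/cTAS motifs,
the conserved sequence blocks CSB-F..A of the central conserved domain
and CSB-1..3 downstream of it), the light-strand replication origin
stem-loop inside the WANCY tRNA cluster, tRNA cloverleaf plausibility,
and discovery of supernumerary (duplicated) tRNA genes.

The repeat finder is a seed-and-extend approximate tandem detector and
the tRNA assessor a structural plausibility heuristic; both report
rather than reject borderline cases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

from Bio import Align

from .model import (
    CANONICAL_GENE_ORDER,
    CANONICAL_TRNAS,
    GeneFeature,
    Mitogenome,
    reverse_complement,
)

__all__ = [
    "TandemRepeat",
    "CsbHit",
    "ControlRegionAnnotation",
    "StemLoop",
    "TrnaAssessment",
    "NovelGeneEvent",
    "load_csb_consensus",
    "find_tandem_repeats",
    "scan_csb",
    "derive_consensus",
    "consensus_with_ties",
    "annotate_control_region",
    "linearized_control_region",
    "find_ol_stemloop",
    "assess_trna",
    "detect_novel_trnas",
    "global_identity",
]

TAS_MOTIF = "TACAT"
CTAS_MOTIF = reverse_complement(TAS_MOTIF)  # ATGTA

_CCD_ORDER = ("F", "E", "D", "C", "B", "A")
_DOWNSTREAM_ORDER = ("1", "2", "3")


def load_csb_consensus() -> dict[str, str]:
    """The packaged conserved-sequence-block consensus set (block -> DNA)."""
    text = (resources.files("mitocomp") / "data" / "csb_consensus.tsv").read_text()
    out: dict[str, str] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        block, consensus = line.split("\t")[:2]
        out[block] = consensus
    return out


# ---------------------------------------------------------------------------
# Tandem repeats (ETAS)
# ---------------------------------------------------------------------------

@dataclass
class TandemRepeat:
    start: int
    period: int
    copy_number: float
    unit_sequence: str
    mismatches: int
    contains_TAS: bool = field(init=False)
    contains_cTAS: bool = field(init=False)
    hairpin_capable: bool = field(init=False)

    def __post_init__(self) -> None:
        doubled = self.unit_sequence * 2
        self.contains_TAS = TAS_MOTIF in doubled
        self.contains_cTAS = CTAS_MOTIF in doubled
        # a TAS unit followed by its reverse-complement motif can pair
        # into a stable hairpin terminating heavy-strand replication
        self.hairpin_capable = self.contains_TAS and self.contains_cTAS

    @property
    def end(self) -> int:
        return self.start + int(round(self.copy_number * self.period))


def find_tandem_repeats(seq: str, min_period: int = 5, max_period: int = 150,
                        min_copies: float = 2.0,
                        max_mismatch_frac: float = 0.2) -> list[TandemRepeat]:
    """Seed-and-extend approximate tandem repeat detection.

    For each candidate period ``p`` the sequence is compared against
    itself shifted by ``p``; maximal stretches whose mismatch fraction
    stays within ``max_mismatch_frac`` and that span at least
    ``min_copies`` units are reported.  Overlapping calls at different
    periods are resolved greedily by tract length (ties to the smaller
    period), yielding maximal non-overlapping tracts.
    """
    if min_period < 1:
        raise ValueError("min_period must be >= 1")
    n = len(seq)
    candidates: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        i = 0
        while i < n - p:
            if seq[i] != seq[i + p]:
                i += 1
                continue
            # extend a matching run, tolerating mismatches within budget;
            # the endpoint maximizes matches - 4*mismatches so the tract
            # does not creep into random flanking sequence
            j, mism, score = i, 0, 0
            best_j, best_mism, best_score = i, 0, 1
            while j < n - p:
                if seq[j] != seq[j + p]:
                    if (mism + 1) > max_mismatch_frac * (j + 1 - i):
                        break
                    mism += 1
                    score -= 4
                else:
                    score += 1
                    if score > best_score:
                        best_j, best_mism, best_score = j, mism, score
                j += 1
            tract_len = best_j - i + 1 + p
            copies = tract_len / p
            if copies >= min_copies:
                candidates.append(TandemRepeat(
                    start=i, period=p, copy_number=round(copies, 2),
                    unit_sequence=seq[i:i + p], mismatches=best_mism))
                i = best_j + 1
            else:
                i += 1
    # greedy selection of non-overlapping tracts: longest first, then
    # smallest period so a period-p repeat is not re-reported at 2p
    candidates.sort(key=lambda r: (-(r.end - r.start), r.period, r.start))
    chosen: list[TandemRepeat] = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.start)
    return chosen


# ---------------------------------------------------------------------------
# Conserved sequence blocks
# ---------------------------------------------------------------------------

@dataclass
class CsbHit:
    block_id: str
    start: int
    mismatches: int
    matched_sequence: str


def _best_window(seq: str, consensus: str) -> tuple[int, int]:
    """Leftmost minimum-Hamming-distance window (no gaps)."""
    m = len(consensus)
    best_pos, best_mism = -1, m + 1
    for i in range(len(seq) - m + 1):
        mism = sum(1 for a, b in zip(seq[i:i + m], consensus) if a != b)
        if mism < best_mism:
            best_pos, best_mism = i, mism
            if mism == 0:
                break
    return best_pos, best_mism


def scan_csb(cr_seq: str, consensus_set: dict[str, str] | None = None,
             tolerance: float = 0.2) -> list[CsbHit]:
    """Best-scoring window per conserved block, by Hamming distance.

    A block is reported only when its best window has at most
    ``ceil(tolerance * len(consensus))`` mismatches.  At tolerance 0
    this reduces to exact substring search.  Overlapping hits for two
    blocks are both reported, with an order-violation warning.
    """
    cr_seq = cr_seq.upper()
    if consensus_set is None:
        consensus_set = load_csb_consensus()
    hits: list[CsbHit] = []
    for block in list(_CCD_ORDER) + list(_DOWNSTREAM_ORDER):
        if block not in consensus_set:
            continue
        consensus = consensus_set[block].upper()
        if len(cr_seq) < len(consensus):
            continue
        pos, mism = _best_window(cr_seq, consensus)
        if pos >= 0 and mism <= math.ceil(tolerance * len(consensus)):
            hits.append(CsbHit(block, pos, mism, cr_seq[pos:pos + len(consensus)]))
    hits.sort(key=lambda h: h.start)
    by_block = {h.block_id: h for h in hits}
    expected = [b for b in list(_CCD_ORDER) + list(_DOWNSTREAM_ORDER) if b in by_block]
    observed = [h.block_id for h in hits]
    if observed != expected:
        warnings.warn(f"CSB hits out of canonical order: found {observed}, "
                      f"expected {expected}")
    for a, b in zip(hits, hits[1:]):
        if a.start + len(a.matched_sequence) > b.start:
            warnings.warn(f"CSB-{a.block_id} and CSB-{b.block_id} best hits overlap")
    return hits


def consensus_with_ties(aligned: list[str]) -> tuple[str, list[int]]:
    """Column-wise majority base over non-gap characters.

    Ties break by fixed base order A<C<G<T; tied column indices are
    returned alongside.  All-gap columns are excluded.
    """
    if len(aligned) < 3:
        raise ValueError("need at least 3 sequences to derive a consensus")
    if len({len(s) for s in aligned}) != 1:
        raise ValueError("sequences must be pre-aligned to equal length")
    cons, ties = [], []
    for col in range(len(aligned[0])):
        counts: dict[str, int] = {}
        for s in aligned:
            c = s[col].upper()
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            continue  # all-gap column excluded
        best = max(counts.values())
        winners = sorted(c for c, k in counts.items() if k == best)
        if len(winners) > 1:
            ties.append(len(cons))
        cons.append(winners[0])
    return "".join(cons), ties


def derive_consensus(aligned_crs: list[str],
                     block_spans: dict[str, tuple[int, int]] | None = None
                     ) -> dict[str, str]:
    """Majority consensus per conserved block from pre-aligned sequences.

    ``block_spans`` gives each block's span in alignment coordinates;
    without it a single consensus over the whole alignment is returned
    under the key ``"all"``.
    """
    if block_spans is None:
        cons, _ = consensus_with_ties(aligned_crs)
        return {"all": cons}
    out = {}
    for block, (start, end) in block_spans.items():
        cons, _ = consensus_with_ties([s[start:end] for s in aligned_crs])
        out[block] = cons
    return out


@dataclass
class ControlRegionAnnotation:
    """Structural annotation of one control region sequence."""

    cr_span: tuple[int, int]
    etas_repeats: list[TandemRepeat]
    csb_hits: list[CsbHit]
    domain_boundaries: dict[str, tuple[int, int]]

    def hit(self, block_id: str) -> CsbHit | None:
        for h in self.csb_hits:
            if h.block_id == block_id:
                return h
        return None


def linearized_control_region(genome: Mitogenome) -> tuple[str, tuple[int, int]]:
    """The control region sequence linearized at its tRNA-Pro / tRNA-Phe
    boundary (the CR sits between these two tRNAs and may wrap the
    circular origin)."""
    feat = genome.get_feature("CR")
    return genome.heavy_strand_slice(feat), (feat.start, feat.end)


def annotate_control_region(cr_seq: str, cr_span: tuple[int, int] = (0, 0),
                            consensus_set: dict[str, str] | None = None,
                            tolerance: float = 0.2,
                            min_repeat_period: int = 5,
                            min_repeat_copies: float = 2.0) -> ControlRegionAnnotation:
    """Full structural annotation of a control region.

    Domain boundaries follow the conserved-block architecture: the ETAS
    (repeat) domain runs from the CR 5' end to CSB-F, which demarcates
    the start of the central conserved domain; the CCD ends at CSB-A and
    the downstream segment (CSB-1..3) follows.  When CSB-F is absent the
    ETAS domain's 3' limit is undefined and reported as the CR end.
    """
    hits = scan_csb(cr_seq, consensus_set=consensus_set, tolerance=tolerance)
    by_block = {h.block_id: h for h in hits}
    n = len(cr_seq)
    f_hit, a_hit = by_block.get("F"), by_block.get("A")
    etas_end = f_hit.start if f_hit else n
    domains = {"ETAS": (0, etas_end)}
    if f_hit and a_hit:
        ccd_end = a_hit.start + len(a_hit.matched_sequence)
        domains["CCD"] = (f_hit.start, ccd_end)
        domains["downstream"] = (ccd_end, n)
    repeats = [r for r in find_tandem_repeats(
        cr_seq[:etas_end], min_period=min_repeat_period,
        min_copies=min_repeat_copies)]
    return ControlRegionAnnotation(cr_span=cr_span, etas_repeats=repeats,
                                   csb_hits=hits, domain_boundaries=domains)


# ---------------------------------------------------------------------------
# Light-strand origin stem-loop
# ---------------------------------------------------------------------------

@dataclass
class StemLoop:
    span: tuple[int, int]
    stem_length_bp: int
    stem_mismatches: int
    loop_sequence: str
    stem_gc_fraction: float
    loop_t_fraction: float
    has_GCCGG_motif: bool
    flank_pyrimidine_fraction: float


def find_ol_stemloop(region: str, min_stem: int = 5, max_stem: int = 12,
                     min_loop: int = 3, max_loop: int = 16,
                     max_stem_mismatch: int = 1) -> StemLoop | None:
    """Highest-scoring hairpin in a WANCY-cluster spacer region.

    The light-strand replication origin folds into a stem-loop with a
    GC-rich stem and T-rich loop; candidates are scored by
    ``stem_pairs * (1 + stem_GC_fraction) + loop_T_fraction`` and the
    stem arms must be reverse-complementary with at most one mismatch.
    Returns ``None`` when no stem of at least ``min_stem`` pairs forms.
    The conserved GCCGG motif at the stem base and the pyrimidine
    fraction of the 10 bp 5' flank are recorded.
    """
    region = region.upper()
    n = len(region)
    best: StemLoop | None = None
    best_score = -1.0
    for k in range(min_stem, max_stem + 1):
        for loop_len in range(min_loop, max_loop + 1):
            span_len = 2 * k + loop_len
            for i in range(0, n - span_len + 1):
                arm5 = region[i:i + k]
                arm3 = region[i + k + loop_len:i + span_len]
                mism = sum(1 for a, b in zip(arm5, reverse_complement(arm3))
                           if a != b)
                if mism > max_stem_mismatch:
                    continue
                loop = region[i + k:i + k + loop_len]
                stem = arm5 + arm3
                gc = sum(stem.count(b) for b in "GC") / len(stem)
                t_frac = loop.count("T") / len(loop)
                score = (k - mism) * (1.0 + gc) + t_frac
                if score > best_score:
                    flank = region[max(0, i - 10):i]
                    pyr = (sum(flank.count(b) for b in "CT") / len(flank)
                           if flank else 0.0)
                    base_zone = region[max(0, i - 5):i + k] + region[
                        i + k + loop_len:min(n, i + span_len + 5)]
                    best = StemLoop(
                        span=(i, i + span_len), stem_length_bp=k,
                        stem_mismatches=mism, loop_sequence=loop,
                        stem_gc_fraction=gc, loop_t_fraction=t_frac,
                        has_GCCGG_motif="GCCGG" in base_zone,
                        flank_pyrimidine_fraction=pyr)
                    best_score = score
    return best


# ---------------------------------------------------------------------------
# tRNA cloverleaf heuristic
# ---------------------------------------------------------------------------

@dataclass
class TrnaAssessment:
    gene: str
    cloverleaf_ok: bool
    missing_arm: str  # none | D-arm | T-arm
    anticodon: str  # RNA sense
    reason: str = ""
    best_intragenome_match: tuple[str, float] | None = None


def _hairpin_in(seq: str, stems: range, loops: range,
                max_mism: int = 1) -> bool:
    for k in stems:
        allowed = 0 if k <= 3 else max_mism
        for loop_len in loops:
            span = 2 * k + loop_len
            for i in range(0, len(seq) - span + 1):
                arm5 = seq[i:i + k]
                arm3 = seq[i + k + loop_len:i + span]
                mism = sum(1 for a, b in zip(arm5, reverse_complement(arm3))
                           if a != b)
                if mism <= allowed:
                    return True
    return False


def assess_trna(seq: str, gene: str = "tRNA") -> TrnaAssessment:
    """Structural plausibility check of a tRNA gene sequence.

    Heuristic arm-finding: an acceptor stem of >=6 pairs (<=1 mismatch)
    between the 5' and 3' ends, an anticodon arm with a 5-pair stem and
    a 7-base loop, and D- and T-arm hairpins in the regions flanking the
    anticodon arm.  The anticodon is read from positions 3-5 of the
    anticodon loop (RNA sense).  A cloverleaf needs acceptor + anticodon
    arms plus at least one of the D-/T-arms; a missing D-arm is the
    'truncated cloverleaf' seen in metazoan tRNA-Ser(AGY).
    """
    seq = seq.upper()
    if not 55 <= len(seq) <= 95:
        return TrnaAssessment(gene, False, "none", "",
                              reason=f"length {len(seq)} outside 55..95")
    # acceptor stem: 7 terminal bases each side, >=6 pairs
    acc_mism = sum(1 for a, b in zip(seq[:7], reverse_complement(seq[-7:]))
                   if a != b)
    acceptor_ok = acc_mism <= 1
    # anticodon arm: 5-pair stem around a 7-base loop, scanned over the core
    ac_candidates = []
    for i in range(7, len(seq) - 24):
        arm5, loop, arm3 = seq[i:i + 5], seq[i + 5:i + 12], seq[i + 12:i + 17]
        mism = sum(1 for a, b in zip(arm5, reverse_complement(arm3)) if a != b)
        if mism <= 1:
            centre = abs((i + 8.5) - len(seq) / 2)
            ac_candidates.append((mism, centre, i, loop))
    if not ac_candidates:
        return TrnaAssessment(gene, False, "none", "",
                              reason="no anticodon arm found")
    _, _, ac_start, ac_loop = min(ac_candidates)
    anticodon = ac_loop[2:5].replace("T", "U")
    d_region = seq[7:ac_start]
    t_region = seq[ac_start + 17:len(seq) - 7]
    d_ok = _hairpin_in(d_region, stems=range(3, 6), loops=range(4, 11))
    t_ok = _hairpin_in(t_region, stems=range(3, 6), loops=range(4, 11))
    if d_ok and t_ok:
        missing = "none"
    elif t_ok:
        missing = "D-arm"
    elif d_ok:
        missing = "T-arm"
    else:
        missing = "D-arm"  # neither found: report the commoner loss
    ok = acceptor_ok and (d_ok or t_ok)
    reason = "" if acceptor_ok else f"acceptor stem has {acc_mism} mismatches"
    return TrnaAssessment(gene, ok, missing, anticodon, reason=reason)


# ---------------------------------------------------------------------------
# Supernumerary tRNA discovery
# ---------------------------------------------------------------------------

@dataclass
class NovelGeneEvent:
    event_type: str  # tandem_duplication_with_anticodon_shift | long_range_duplication_to_CR | none
    extra_gene: str
    extra_span: tuple[int, int]
    source_gene: str
    identity_to_source: float  # percent
    notes: str = ""


_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=-1,
    open_gap_score=-2, extend_gap_score=-2)


def global_identity(a: str, b: str) -> float:
    """Percent identity of the best global alignment
    (match +1 / mismatch -1 / gap -2); identity = matches / alignment
    columns, gap columns included."""
    aln = _ALIGNER.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns


def _canonical_predecessor(name: str) -> str | None:
    names = [n for n, _, _ in CANONICAL_GENE_ORDER]
    if name in names:
        i = names.index(name)
        return names[i - 1]
    return None


def _within(feature: GeneFeature, container: GeneFeature, n: int) -> bool:
    if container.wraps_origin:
        return feature.start >= container.start or feature.end <= container.end
    return feature.start >= container.start and feature.end <= container.end


def detect_novel_trnas(genome: Mitogenome,
                       identity_threshold: float = 70.0) -> list[NovelGeneEvent]:
    """Find supernumerary tRNAs and classify their duplication mechanism.

    Any tRNA beyond the canonical 22-gene complement is globally aligned
    to every other tRNA in the same genome.  The event is a tandem
    duplication (with anticodon shift) when the best match is an
    adjacent gene at identity >= threshold — the slipped-strand
    mispairing signature — and a long-range duplication when the extra
    copy lies inside the control region and matches a distal gene.  An
    extra copy matching nothing above threshold is reported with
    ``event_type='none'`` and flagged for review.
    """
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    trnas = [f for f in feats if f.ftype == "tRNA"]
    counts: dict[str, int] = {}
    for f in trnas:
        counts[f.name] = counts.get(f.name, 0) + 1
    canonical_counts = {name: 1 for name in CANONICAL_TRNAS}

    extras: list[GeneFeature] = []
    for name, k in counts.items():
        allowed = canonical_counts.get(name, 0)
        if k <= allowed:
            continue
        copies = [f for f in trnas if f.name == name]
        # the supernumerary copy is the one out of canonical neighbour context
        pred = _canonical_predecessor(name)
        def in_context(f: GeneFeature) -> bool:
            i = feats.index(f)
            return pred is not None and feats[i - 1].name == pred
        out_of_context = [f for f in copies if not in_context(f)]
        keep = out_of_context if out_of_context else copies
        extras.extend(keep[: k - allowed] if len(keep) > k - allowed else keep)

    cr = next((f for f in genome.features if f.name == "CR"), None)
    events: list[NovelGeneEvent] = []
    for extra in extras:
        extra_seq = genome.feature_sequence(extra)
        best_name, best_id, best_feat = "", -1.0, None
        for other in trnas:
            if other is extra:
                continue
            ident = global_identity(extra_seq, genome.feature_sequence(other))
            if ident > best_id:
                best_name, best_id, best_feat = other.name, ident, other
        span = (extra.start, extra.end)
        if best_id < identity_threshold:
            events.append(NovelGeneEvent(
                "none", extra.name, span, best_name, round(best_id, 1),
                notes="no canonical tRNA matches above the identity "
                      "threshold; flagged for review"))
            continue
        i_extra = feats.index(extra)
        adjacent = best_feat in (
            feats[i_extra - 1], feats[(i_extra + 1) % len(feats)],
            feats[i_extra - 2], feats[(i_extra + 2) % len(feats)])
        in_cr = cr is not None and _within(extra, cr, genome.length_bp)
        if in_cr and not adjacent:
            etype = "long_range_duplication_to_CR"
            note = ("extra copy inside the control region matching a distal "
                    "gene; consistent with illicit tRNA priming of replication")
        elif adjacent:
            etype = "tandem_duplication_with_anticodon_shift"
            note = ("best match is the adjacent gene; consistent with tandem "
                    "duplication by slipped-strand mispairing")
        else:
            etype = "none"
            note = "match above threshold but neither adjacent nor inside the CR"
        events.append(NovelGeneEvent(etype, extra.name, span, best_name,
                                     round(best_id, 1), notes=note))
    return events
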