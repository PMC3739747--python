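"""Ground-truthed synthetic mitogenome clades.

The generator assembles a root genome following the canonical 37-gene
vertebrate mitochondrial order with realistic strand assignments, gene
overlaps (ATP8/ATP6 -10, ND4L/ND4 -7, ND5/ND6 -4, ATP6/COIII -1),
incomplete stop codons upstream of tRNAs, a control region carrying a
tandem-repeat ETAS domain with TAS/cTAS motifs, the conserved sequence
blocks F..A and 1..3, and a light-strand origin stem-loop in the WANCY
cluster.  The root is then evolved down a tree under per-class
substitution rates with codon-position multipliers, and configured
tRNA duplication events are injected per taxon, so every analysis stage
can be validated against known ground truth.

Substitutions follow an F81 process (single exchangeability, the
replacement base drawn from the equilibrium frequencies), the
composition-preserving extension of Jukes–Cantor; with uniform
frequencies it reduces exactly to JC69.  CDS sites additionally reject
mutations that would create internal stop codons or alter start/stop
codons, and non-synonymous changes are accepted with probability
``omega`` (purifying selection).  Planted regulatory motifs (TAS, CSB
blocks, the O_L stem-loop) are held invariant, and the ETAS repeat
tract evolves concertedly — all copies stay identical within a genome,
as slippage-driven homogenization keeps them in real mtDNA.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skbio import TreeNode

from .genetic_code import is_stop
from .model import CANONICAL_GENE_ORDER, GeneFeature, Mitogenome, reverse_complement
from .structure import assess_trna, load_csb_consensus

__all__ = [
    "SimulationConfig",
    "DuplicationEvent",
    "SimulatedClade",
    "simulate_clade",
    "inject_duplication",
    "random_cds",
    "simulate_coding_pair",
    "build_trna",
    "ANTICODON_OFFSET",
    "ANTICODON_OFFSET_TRUNCATED",
    "GENE_LENGTHS",
    "TRNA_ANTICODONS_DNA",
]

# ---------------------------------------------------------------------------
# Canonical parameters of the emitted genomes
# ---------------------------------------------------------------------------

#: Fixed gene lengths (bp), each inside the range observed across
#: canonical grouper-type mitogenomes.
GENE_LENGTHS: dict[str, int] = {
    "tRNA-Phe": 70, "12S rRNA": 955, "tRNA-Val": 70, "16S rRNA": 1700,
    "tRNA-Leu(UUR)": 74, "ND1": 975, "tRNA-Ile": 70, "tRNA-Gln": 70,
    "tRNA-Met": 70, "ND2": 1046, "tRNA-Trp": 70, "tRNA-Ala": 70,
    "tRNA-Asn": 70, "OL": 38, "tRNA-Cys": 70, "tRNA-Tyr": 70,
    "COI": 1551, "tRNA-Ser(UCN)": 70, "tRNA-Asp": 70, "COII": 691,
    "tRNA-Lys": 70, "ATP8": 168, "ATP6": 684, "COIII": 786,
    "tRNA-Gly": 70, "ND3": 349, "tRNA-Arg": 70, "ND4L": 297,
    "ND4": 1381, "tRNA-His": 70, "tRNA-Ser(AGY)": 70,
    "tRNA-Leu(CUN)": 70, "ND5": 1839, "ND6": 522, "tRNA-Glu": 70,
    "CYTB": 1141, "tRNA-Thr": 70, "tRNA-Pro": 70,
}

#: Start codons: ATG throughout except COI (GTG, as in most metazoans)
#: and ATP6 (CTG, the derived epinephelid state).
CDS_START: dict[str, str] = {
    "ND1": "ATG", "ND2": "ATG", "COI": "GTG", "COII": "ATG", "ATP8": "ATG",
    "ATP6": "CTG", "COIII": "ATG", "ND3": "ATG", "ND4L": "ATG",
    "ND4": "ATG", "ND5": "ATG", "ND6": "ATG", "CYTB": "ATG",
}

#: Terminal residues: full TAA stops, or incomplete T/TA completed by
#: post-transcriptional polyadenylation (gene length mod 3 matches).
CDS_STOP: dict[str, str] = {
    "ND1": "TAA", "ND2": "TA", "COI": "TAA", "COII": "T", "ATP8": "TAA",
    "ATP6": "TAA", "COIII": "TAA", "ND3": "T", "ND4L": "TAA", "ND4": "T",
    "ND5": "TAA", "ND6": "TAA", "CYTB": "T",
}

#: Configured overlaps (bp) between adjacent genes, keyed
#: (upstream, downstream) in heavy-strand order.
DEFAULT_OVERLAPS: dict[tuple[str, str], int] = {
    ("ATP8", "ATP6"): 10,
    ("ATP6", "COIII"): 1,
    ("ND4L", "ND4"): 7,
    ("ND5", "ND6"): 4,
}

#: Anticodons in DNA sense as they appear 5'->3' in the anticodon loop.
TRNA_ANTICODONS_DNA: dict[str, str] = {
    "tRNA-Phe": "GAA", "tRNA-Val": "TAC", "tRNA-Leu(UUR)": "TAA",
    "tRNA-Ile": "GAT", "tRNA-Gln": "TTG", "tRNA-Met": "CAT",
    "tRNA-Trp": "TCA", "tRNA-Ala": "TGC", "tRNA-Asn": "GTT",
    "tRNA-Cys": "GCA", "tRNA-Tyr": "GTA", "tRNA-Ser(UCN)": "TGA",
    "tRNA-Asp": "GTC", "tRNA-Lys": "TTT", "tRNA-Gly": "TCC",
    "tRNA-Arg": "TCG", "tRNA-His": "GTG", "tRNA-Ser(AGY)": "GCT",
    "tRNA-Leu(CUN)": "TAG", "tRNA-Glu": "TTC", "tRNA-Thr": "TGT",
    "tRNA-Pro": "TGG",
}

# cloverleaf template layout (full): acceptor 7 | D-arm 4+8+4 | AC stem 5 |
# loop 2+anticodon+2 | AC stem 5 | variable 6 | T-arm 5+7+5 | acceptor 7
ANTICODON_OFFSET = 7 + 16 + 5 + 2  # = 30
# truncated (no D-arm, tRNA-Ser(AGY)-like): connector 4 replaces the D-arm
ANTICODON_OFFSET_TRUNCATED = 7 + 4 + 5 + 2  # = 18


@dataclass
class DuplicationEvent:
    """A tRNA duplication to inject into one taxon's genome.

    ``mode='tandem'`` copies the source gene immediately downstream of
    itself and mutates the copy's anticodon (slipped-strand mispairing
    followed by anticodon switch); ``mode='cr'`` inserts a strand-flipped
    copy at the control-region midpoint (long-range duplication through
    illicit tRNA priming of replication).
    """

    taxon: str
    mode: str  # "tandem" | "cr"
    source_gene: str
    new_name: str = ""
    anticodon_dna: str = ""  # tandem mode: new anticodon, DNA sense
    anticodon_offset: int | None = ANTICODON_OFFSET

    def __post_init__(self) -> None:
        if self.mode not in ("tandem", "cr"):
            raise ValueError(f"unknown duplication mode {self.mode!r}")
        if self.mode == "tandem" and not (self.new_name and self.anticodon_dna):
            raise ValueError("tandem events need new_name and anticodon_dna")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_taxa: int = 6
    tree_newick: str | None = None  # random ultrametric tree if None
    #: per-class substitution proposal rates (expected proposals per site
    #: over a branch of length 1); CDS classes are thinned by ``omega``
    rates: dict[str, float] = field(default_factory=lambda: {
        "rRNA": 0.02, "tRNA": 0.025, "cds_slow": 0.06, "cds_mid": 0.12,
        "cds_fast": 0.24, "CR": 0.15})
    #: rate class per protein gene: cytochrome oxidases slow, ND6/ATP8 fast
    gene_classes: dict[str, str] = field(default_factory=lambda: {
        "COI": "cds_slow", "COII": "cds_slow", "COIII": "cds_slow",
        "ND6": "cds_fast", "ATP8": "cds_fast"})
    #: acceptance probability of non-synonymous changes (purifying selection)
    omega: float = 0.35
    #: relative proposal rates at codon positions 1/2/3 (3rd > 1st > 2nd)
    codon_position_multipliers: tuple[float, float, float] = (1.0, 0.4, 1.6)
    #: heavy-strand equilibrium base frequencies (C > G bias)
    base_freqs: dict[str, float] = field(default_factory=lambda: {
        "A": 0.29, "T": 0.27, "G": 0.16, "C": 0.28})
    #: coding-sense frequencies for light-strand genes; None mirrors the
    #: heavy-strand set (A<->T, G<->C), i.e. asymmetry is a strand property
    base_freqs_light: dict[str, float] | None = None
    overlaps: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_OVERLAPS))
    etas_unit_length: int = 40     # repetitive elements span 15..134 bp
    etas_copies: int = 6           # species show 2..22 tandem copies
    ol_length: int = 38            # O_L stretch of 33..43 nt
    cr_length: int = 900           # CR sizes run 721..1264 bp
    cr_wraps_origin: bool = False
    duplication_events: list[DuplicationEvent] = field(default_factory=list)

    def validate(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be >= 0")
        if self.etas_copies < 2:
            raise ValueError("etas_copies must be >= 2")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must lie in [0, 1]")
        if not 33 <= self.ol_length <= 43:
            raise ValueError("ol_length outside the observed 33..43 range")
        if self.etas_unit_length < 15:
            raise ValueError("etas_unit_length below the observed minimum 15")
        for (up, down), o in self.overlaps.items():
            if o >= min(GENE_LENGTHS[up], GENE_LENGTHS[down]):
                raise ValueError(f"overlap {up}/{down}={o} longer than a gene")
        needed = (self.etas_copies * self.etas_unit_length + 120
                  + sum(len(c) for c in load_csb_consensus().values()))
        if self.cr_length < needed:
            raise ValueError(f"cr_length {self.cr_length} too short for the "
                             f"configured ETAS and CSB layout (needs >= {needed})")


@dataclass
class SimulatedClade:
    genomes: list[Mitogenome]
    truth: dict[str, Any]
    tree_newick: str
    config: SimulationConfig

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, default=str)


# ---------------------------------------------------------------------------
# Random sequence primitives
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, freqs: dict[str, float], k: int = 1) -> str:
    bases = np.array(list(freqs))
    p = np.array(list(freqs.values()), dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(bases, size=k, p=p))


def random_cds(rng: np.random.Generator, n_codons: int,
               freqs: dict[str, float] | None = None,
               position_freqs: dict[int, dict[str, float]] | None = None,
               start_codon: str | None = None) -> str:
    """Random stop-free coding sequence under the vertebrate mito code.

    Bases draw i.i.d. from ``freqs`` (optionally overridden per codon
    position via ``position_freqs`` keyed 1..3).  A drawn stop codon is
    repaired by redrawing one of its bases — a minimal intervention that
    keeps the marginal composition close to the target frequencies.
    """
    freqs = freqs or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    pf = {p: (position_freqs or {}).get(p, freqs) for p in (1, 2, 3)}
    codons = []
    for _ in range(n_codons):
        codon = [_draw(rng, pf[1]), _draw(rng, pf[2]), _draw(rng, pf[3])]
        while is_stop("".join(codon)):
            p = int(rng.integers(3))
            codon[p] = _draw(rng, pf[p + 1])
        codons.append("".join(codon))
    cds = "".join(codons)
    if start_codon:
        cds = start_codon + cds[3:]
    return cds


def _gen_cds(rng: np.random.Generator, length: int, start_codon: str,
             stop_tail: str, freqs: dict[str, float],
             fixed: dict[int, str] | None = None,
             validator=None, max_tries: int = 500) -> str:
    """A CDS of ``length`` bp with fixed start/stop, optional pinned
    positions, no internal stops, and an optional extra validator
    (used for cross-frame constraints in gene overlaps)."""
    pins: dict[int, str] = dict(fixed or {})
    for i, b in enumerate(start_codon):
        pins[i] = b
    for i, b in enumerate(stop_tail):
        pins[length - len(stop_tail) + i] = b
    full_stop = length % 3 == 0 and (
        len(stop_tail) == 3
        or (all(length - 3 + i in pins for i in range(3))
            and is_stop("".join(pins[length - 3 + i] for i in range(3)))))
    n_codons = length // 3
    for _ in range(max_tries):
        seq = [pins.get(i) or _draw(rng, freqs) for i in range(length)]
        ok = True
        for ci in range(n_codons):
            if full_stop and ci == n_codons - 1:
                continue  # terminal stop codon is allowed
            lo = 3 * ci
            tries = 0
            while is_stop("".join(seq[lo:lo + 3])):
                free = [p for p in (lo, lo + 1, lo + 2) if p not in pins]
                tries += 1
                if not free or tries > 50:
                    ok = False
                    break
                p = free[int(rng.integers(len(free)))]
                seq[p] = _draw(rng, freqs)
            if not ok:
                break
        if not ok:
            continue
        s = "".join(seq)
        if validator is None or validator(s):
            return s
    raise RuntimeError("could not satisfy CDS constraints; config contradictory?")


def _frame_clean(seq: str, frame_start: int, terminal_stop_at: int | None = None) -> bool:
    """No stop codons in the frame starting at ``frame_start`` except an
    allowed terminal one."""
    for lo in range(frame_start, len(seq) - 2, 3):
        if lo == terminal_stop_at:
            continue
        if is_stop(seq[lo:lo + 3]):
            return False
    return True


def build_trna(rng: np.random.Generator, anticodon_dna: str,
               freqs: dict[str, float], truncated: bool = False,
               length: int = 70, max_tries: int = 200) -> str:
    """A cloverleaf-plausible tRNA gene sequence (coding sense).

    Layout: acceptor stem 7 bp | D-arm (4+8+4; replaced by a 4-base
    connector when ``truncated``) | anticodon arm 5+7+5 with the
    anticodon at loop positions 3-5 | variable region | T-arm 5+7+5 |
    acceptor 3' arm.  Candidates are rejected until the cloverleaf
    assessor recovers the intended structure and anticodon, so the
    emitted gene is plausible by construction.
    """
    core = 7 + (4 if truncated else 16) + 17 + 17 + 7
    var_len = length - core
    if var_len < 1:
        raise ValueError(f"tRNA length {length} too short for the template")
    gc_rich = {"A": 0.12, "T": 0.12, "G": 0.38, "C": 0.38}
    for _ in range(max_tries):
        acc = _draw(rng, gc_rich, 7)
        ac_stem = _draw(rng, gc_rich, 5)
        t_stem = _draw(rng, gc_rich, 5)
        ac_loop = _draw(rng, freqs, 2) + anticodon_dna + _draw(rng, freqs, 2)
        t_loop = _draw(rng, freqs, 7)
        var = _draw(rng, freqs, var_len)
        if truncated:
            d_part = _draw(rng, freqs, 4)
        else:
            d_stem = _draw(rng, gc_rich, 4)
            d_part = d_stem + _draw(rng, freqs, 8) + reverse_complement(d_stem)
        seq = (acc + d_part + ac_stem + ac_loop + reverse_complement(ac_stem)
               + var + t_stem + t_loop + reverse_complement(t_stem)
               + reverse_complement(acc))
        a = assess_trna(seq)
        want_missing = "D-arm" if truncated else "none"
        if (a.cloverleaf_ok and a.missing_arm == want_missing
                and a.anticodon == anticodon_dna.replace("T", "U")):
            return seq
    raise RuntimeError("failed to build a cloverleaf-plausible tRNA")


# ---------------------------------------------------------------------------
# Root genome assembly
# ---------------------------------------------------------------------------

def _build_control_region(rng: np.random.Generator, cfg: SimulationConfig
                          ) -> tuple[str, dict[str, Any]]:
    """Control region: ETAS repeat tract, CCD with CSB-F..A, then
    CSB-1..3, padded to ``cr_length``.  Returns the sequence and a truth
    map of planted offsets (CR-relative)."""
    csb = load_csb_consensus()
    unit_len = cfg.etas_unit_length
    unit = list(_draw(rng, cfg.base_freqs, unit_len))
    unit[5:10] = "TACAT"           # TAS motif
    if unit_len >= 25:
        unit[20:25] = "ATGTA"      # cTAS: enables TAS/cTAS hairpin pairing
    unit = "".join(unit)
    tract = unit * cfg.etas_copies
    parts = [tract]
    pos = len(tract)
    truth: dict[str, Any] = {
        "etas": {"start": 0, "period": unit_len, "copies": cfg.etas_copies,
                 "unit": unit,
                 "tas_offsets": [i * unit_len + 5 for i in range(cfg.etas_copies)]},
        "csb_offsets": {},
    }
    spacer = _draw(rng, cfg.base_freqs, 20)
    parts.append(spacer)
    pos += 20
    for block in ("F", "E", "D", "C", "B", "A"):
        truth["csb_offsets"][block] = pos
        parts.append(csb[block])
        pos += len(csb[block])
        gap = _draw(rng, cfg.base_freqs, 10)
        parts.append(gap)
        pos += 10
    parts.append(_draw(rng, cfg.base_freqs, 20))
    pos += 20
    for block in ("1", "2", "3"):
        truth["csb_offsets"][block] = pos
        parts.append(csb[block])
        pos += len(csb[block])
        gap = _draw(rng, cfg.base_freqs, 8)
        parts.append(gap)
        pos += 8
    if pos < cfg.cr_length:
        parts.append(_draw(rng, cfg.base_freqs, cfg.cr_length - pos))
    return "".join(parts), truth


def _build_ol(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, dict]:
    """O_L stem-loop: pyrimidine-rich 5' flank, GC-rich stem, T-rich
    loop, and the conserved GCCGG motif at the stem base."""
    stem_arm = "".join(rng.choice(list("GC"), size=8))
    loop = "TTTTTT"
    # last flank base fixed to T so the pyrimidine flank cannot pair with
    # the GCCGG motif and extend the stem past its designed base
    pyr = "".join(rng.choice(list("CT"), size=7)) + "T"
    body = pyr + stem_arm + loop + reverse_complement(stem_arm) + "GCCGG"
    pad = _draw(rng, cfg.base_freqs, cfg.ol_length - len(body))
    seq = body + pad
    truth = {"stem_offset": 8, "stem_length": 8, "loop": loop,
             "gccgg_offset": len(body) - 5}
    return seq, truth


def _mirror_freqs(freqs: dict[str, float]) -> dict[str, float]:
    return {"A": freqs["T"], "T": freqs["A"], "G": freqs["C"], "C": freqs["G"]}


def _root_genome(rng: np.random.Generator, cfg: SimulationConfig
                 ) -> tuple[Mitogenome, dict[str, Any]]:
    freqs = cfg.base_freqs
    freqs_l = cfg.base_freqs_light or _mirror_freqs(freqs)
    strand_of = {name: strand for name, _, strand in CANONICAL_GENE_ORDER}
    truth: dict[str, Any] = {}

    # pre-generate CDS chains whose ends are coupled by overlaps
    pregen: dict[str, str] = {}

    def gen_plain(name: str, fixed=None, validator=None) -> str:
        f = freqs_l if strand_of[name] == "L" else freqs
        return _gen_cds(rng, GENE_LENGTHS[name], CDS_START[name],
                        CDS_STOP[name], f, fixed=fixed, validator=validator)

    # --- ATP8 ->(10) ATP6 ->(1) COIII ------------------------------------
    o86 = cfg.overlaps.get(("ATP8", "ATP6"), 0)
    o63 = cfg.overlaps.get(("ATP6", "COIII"), 0)
    coiii = gen_plain("COIII")
    if o86 == 10:
        # ATP8's terminal TAA sits at ATP6[7:10]; ATP8's frame must stay
        # stop-free across the shared decabase
        atp6 = gen_plain(
            "ATP6", fixed={7: "T", 8: "A", 9: "A"},
            validator=lambda s: _frame_clean(s[:10], frame_start=1,
                                             terminal_stop_at=7))
        atp8 = _gen_cds(rng, GENE_LENGTHS["ATP8"], CDS_START["ATP8"], "",
                        freqs,
                        fixed={GENE_LENGTHS["ATP8"] - o86 + i: b
                               for i, b in enumerate(atp6[:o86])})
    else:
        atp6 = gen_plain("ATP6")
        atp8 = gen_plain("ATP8")
    if o63 == 1 and atp6[-1] != coiii[0]:
        # ATP6's stop ends in A and COIII starts ATG, so a 1 bp overlap
        # is automatically consistent; anything else is a config error
        raise RuntimeError("ATP6/COIII 1 bp overlap inconsistent")
    pregen.update(ATP8=atp8, ATP6=atp6, COIII=coiii)

    # --- ND4L ->(7) ND4 ---------------------------------------------------
    o44 = cfg.overlaps.get(("ND4L", "ND4"), 0)
    if o44 == 7:
        nd4 = gen_plain("ND4", fixed={4: "T", 5: "A", 6: "A"},
                        validator=lambda s: _frame_clean(s[:7], frame_start=1,
                                                         terminal_stop_at=4))
        nd4l = _gen_cds(rng, GENE_LENGTHS["ND4L"], CDS_START["ND4L"], "",
                        freqs,
                        fixed={GENE_LENGTHS["ND4L"] - o44 + i: b
                               for i, b in enumerate(nd4[:o44])})
    else:
        nd4 = gen_plain("ND4")
        nd4l = gen_plain("ND4L")
    pregen.update(ND4L=nd4l, ND4=nd4)

    # --- ND5 ->(4) ND6 (opposite strands) ---------------------------------
    o56 = cfg.overlaps.get(("ND5", "ND6"), 0)
    if o56 == 4:
        # ND6 is light-strand: its genome slice is the reverse complement
        # of its coding sequence.  Pinning the base before its stop to
        # T/C makes the shared tetrabase end in a valid ND5 stop.
        x = "TC"[int(rng.integers(2))]
        nd6_coding = gen_plain("ND6", fixed={GENE_LENGTHS["ND6"] - 4: x})
        nd6_slice = reverse_complement(nd6_coding)
        nd5 = _gen_cds(rng, GENE_LENGTHS["ND5"], CDS_START["ND5"], "", freqs,
                       fixed={GENE_LENGTHS["ND5"] - o56 + i: b
                              for i, b in enumerate(nd6_slice[:o56])})
    else:
        nd6_slice = reverse_complement(gen_plain("ND6"))
        nd5 = gen_plain("ND5")
    pregen.update(ND5=nd5, ND6=nd6_slice)

    cr_seq, cr_truth = _build_control_region(rng, cfg)
    ol_seq, ol_truth = _build_ol(rng, cfg)

    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    prev_name = None
    for name, ftype, strand in CANONICAL_GENE_ORDER:
        if ftype == "CDS":
            h_slice = pregen.pop(name, None)
            if h_slice is None:
                h_slice = gen_plain(name) if strand == "H" else \
                    reverse_complement(gen_plain(name))
            elif strand == "L":
                pass  # already stored as heavy-strand slice
        elif ftype == "tRNA":
            coding = build_trna(rng, TRNA_ANTICODONS_DNA[name],
                                freqs_l if strand == "L" else freqs,
                                truncated=(name == "tRNA-Ser(AGY)"),
                                length=GENE_LENGTHS[name])
            h_slice = reverse_complement(coding) if strand == "L" else coding
        elif ftype == "rRNA":
            h_slice = _draw(rng, freqs, GENE_LENGTHS[name])
        elif name == "OL":
            h_slice = ol_seq
        elif name == "CR":
            h_slice = cr_seq
        else:
            h_slice = _draw(rng, freqs, GENE_LENGTHS[name])

        overlap = cfg.overlaps.get((prev_name, name), 0) if prev_name else 0
        if overlap:
            assert parts and "".join(parts)[-overlap:] == h_slice[:overlap], \
                f"overlap mismatch at {prev_name}/{name}"
            start = pos - overlap
            parts.append(h_slice[overlap:])
            pos = start + len(h_slice)
        else:
            start = pos
            parts.append(h_slice)
            pos += len(h_slice)
        anticodon = (TRNA_ANTICODONS_DNA[name].replace("T", "U")
                     if ftype == "tRNA" else "")
        features.append(GeneFeature(name=name, ftype=ftype, start=start,
                                    end=start + len(h_slice), strand=strand,
                                    anticodon=anticodon))
        prev_name = name

    genome = Mitogenome(id="root", sequence="".join(parts), features=features)
    cr_feat = genome.get_feature("CR")
    ol_feat = genome.get_feature("OL")
    truth["cr"] = {**cr_truth, "span": [cr_feat.start, cr_feat.end]}
    truth["ol"] = {**ol_truth, "span": [ol_feat.start, ol_feat.end]}
    return genome, truth


# ---------------------------------------------------------------------------
# Evolution down the tree
# ---------------------------------------------------------------------------

def _random_ultrametric_tree(rng: np.random.Generator, n: int) -> str:
    """Random ultrametric topology of depth 1.0 built by sequential
    random joins; merge heights are kept >= 0.05 apart so internal
    branches carry signal."""
    while True:
        heights = np.sort(rng.uniform(0.25, 1.0, size=n - 1))
        heights[-1] = 1.0
        if n == 2 or np.all(np.diff(heights) >= 0.05):
            break
    clusters: list[tuple[str, float]] = [(f"taxon_{i + 1}", 0.0) for i in range(n)]
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (na, ha), (nb, hb) = clusters[i], clusters[j]
        merged = (f"({na}:{h - ha:.6f},{nb}:{h - hb:.6f})", float(h))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters[0][0] + ";"


class _SiteModel:
    """Per-site proposal rates plus constraint metadata for one root genome."""

    def __init__(self, genome: Mitogenome, truth: dict, cfg: SimulationConfig):
        n = genome.length_bp
        self.rate = np.full(n, cfg.rates["CR"], dtype=float)  # spacers evolve freely
        self.frozen = np.zeros(n, dtype=bool)
        self.cds_cover: dict[int, list[tuple[int, int, str, int, str]]] = {}
        m1, m2, m3 = cfg.codon_position_multipliers
        for f in genome.features:
            span = np.arange(f.start, f.end)
            if f.ftype == "rRNA":
                self.rate[span] = cfg.rates["rRNA"]
            elif f.ftype == "tRNA":
                self.rate[span] = cfg.rates["tRNA"]
            elif f.ftype == "CDS":
                cls = cfg.gene_classes.get(f.name, "cds_mid")
                base = cfg.rates[cls]
                length = f.end - f.start
                stop_len = 3 if len(CDS_STOP[f.name]) == 3 else length % 3
                for g in span:
                    g = int(g)
                    cpos = (g - f.start) if f.strand == "H" else (f.end - 1 - g)
                    mult = (m1, m2, m3)[cpos % 3]
                    r = base * mult
                    if g in self.cds_cover:
                        r = min(r, self.rate[g])  # overlap: slower frame wins
                    self.rate[g] = r
                    self.cds_cover.setdefault(g, []).append(
                        (f.start, f.end, f.strand, length, CDS_STOP[f.name]))
                    if cpos < 3 or cpos >= length - stop_len:
                        self.frozen[g] = True  # start codon / terminal stop
        # planted regulatory elements stay invariant
        ol = truth["ol"]["span"]
        self.frozen[ol[0]:ol[1]] = True
        cr0 = truth["cr"]["span"][0]
        csb = load_csb_consensus()
        for block, off in truth["cr"]["csb_offsets"].items():
            self.frozen[cr0 + off:cr0 + off + len(csb[block])] = True
        # ETAS tract: concerted evolution handled separately
        et = truth["cr"]["etas"]
        self.etas_start = cr0 + et["start"]
        self.unit_len = et["period"]
        self.copies = et["copies"]
        tract = np.arange(self.etas_start,
                          self.etas_start + self.unit_len * self.copies)
        self.frozen[tract] = True
        self.unit_frozen = np.zeros(self.unit_len, dtype=bool)
        self.unit_frozen[5:10] = True      # TAS
        if self.unit_len >= 25:
            self.unit_frozen[20:25] = True  # cTAS
        self.unit_rate = np.full(self.unit_len, cfg.rates["CR"])

    def codon_at(self, seq: np.ndarray, g: int,
                 cover: tuple[int, int, str, int, str]) -> tuple[str, bool]:
        """The codon containing genome site ``g`` in one covering CDS
        frame, and whether it is an internal (must-not-stop) codon."""
        start, end, strand, length, stop = cover
        cpos = (g - start) if strand == "H" else (end - 1 - g)
        c0 = cpos - cpos % 3
        if c0 + 3 > length:
            return "", False  # incomplete terminal codon
        if strand == "H":
            codon = "".join(seq[start + c0:start + c0 + 3])
        else:
            idx = [end - 1 - c0, end - 2 - c0, end - 3 - c0]
            codon = "".join(
                {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}[seq[i]]
                for i in idx)
        internal = c0 < (length - 3 if len(stop) == 3 else length - length % 3)
        return codon, internal


def _synonymous_change(old_codon: str, new_codon: str) -> bool:
    from .genetic_code import translate_codon
    return translate_codon(old_codon) == translate_codon(new_codon)


def _evolve_branch(seq: np.ndarray, unit: np.ndarray, t: float,
                   model: _SiteModel, cfg: SimulationConfig,
                   rng: np.random.Generator) -> None:
    """Evolve a genome array in place along a branch of length ``t``."""
    pi_bases = np.array(list(cfg.base_freqs))
    pi = np.array(list(cfg.base_freqs.values()), dtype=float)
    pi = pi / pi.sum()
    norm = 1.0 - float(np.sum(pi ** 2))
    lam = model.rate * t / norm
    lam[model.frozen] = 0.0
    hit = rng.random(seq.size) < (1.0 - np.exp(-lam))
    for g in np.nonzero(hit)[0]:
        new = str(rng.choice(pi_bases, p=pi))
        old = seq[g]
        if new == old:
            continue
        covers = model.cds_cover.get(int(g), [])
        if covers:
            ok = True
            nonsyn = False
            for cover in covers:
                codon, internal = model.codon_at(seq, int(g), cover)
                if not codon:
                    continue
                start, end, strand, _, _ = cover
                cpos = (g - start) if strand == "H" else (end - 1 - g)
                within = cpos % 3
                if strand == "H":
                    new_codon = codon[:within] + new + codon[within + 1:]
                else:
                    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}[new]
                    new_codon = codon[:within] + comp + codon[within + 1:]
                if internal and is_stop(new_codon):
                    ok = False
                    break
                if not _synonymous_change(codon, new_codon):
                    nonsyn = True
            if not ok:
                continue
            if nonsyn and rng.random() > cfg.omega:
                continue
        seq[g] = new
    # concerted evolution of the ETAS repeat unit
    lam_u = model.unit_rate * t / norm
    lam_u[model.unit_frozen] = 0.0
    hit_u = rng.random(unit.size) < (1.0 - np.exp(-lam_u))
    for j in np.nonzero(hit_u)[0]:
        unit[j] = str(rng.choice(pi_bases, p=pi))
    for c in range(model.copies):
        lo = model.etas_start + c * model.unit_len
        seq[lo:lo + model.unit_len] = unit


def _rotate(genome: Mitogenome, k: int) -> Mitogenome:
    """Rotate the circular sequence so position ``k`` becomes the origin."""
    n = genome.length_bp
    seq = genome.sequence[k:] + genome.sequence[:k]
    feats = []
    for f in genome.features:
        start = (f.start - k) % n
        end = (f.end - k) % n or n
        wraps = start >= end
        feats.append(GeneFeature(name=f.name, ftype=f.ftype, start=start,
                                 end=end, strand=f.strand,
                                 anticodon=f.anticodon, wraps_origin=wraps))
    g = Mitogenome(id=genome.id, sequence=seq, features=feats)
    g.sort_features()
    return g


# ---------------------------------------------------------------------------
# Duplication events
# ---------------------------------------------------------------------------

def inject_duplication(genome: Mitogenome, event: DuplicationEvent) -> Mitogenome:
    """Apply one tRNA duplication event, shifting downstream coordinates.

    Tandem mode copies the source gene immediately downstream of itself
    and rewrites the copy's anticodon; CR mode inserts a strand-flipped
    copy at the control-region midpoint.
    """
    g = genome.copy()
    src = g.get_feature(event.source_gene)
    src_slice = g.heavy_strand_slice(src)
    if event.mode == "tandem":
        coding = g.feature_sequence(src)
        off = event.anticodon_offset
        if off is None:
            a = assess_trna(coding)
            off = coding.find(a.anticodon.replace("U", "T"))
        coding = coding[:off] + event.anticodon_dna + coding[off + 3:]
        ins_slice = (reverse_complement(coding) if src.strand == "L" else coding)
        ins_at = src.end
        new_feat = GeneFeature(
            name=event.new_name, ftype="tRNA", start=ins_at,
            end=ins_at + len(ins_slice), strand=src.strand,
            anticodon=event.anticodon_dna.replace("T", "U"))
    else:  # cr
        cr = g.get_feature("CR")
        ins_at = cr.start + (cr.end - cr.start) // 2
        ins_slice = reverse_complement(src_slice)
        flipped = "L" if src.strand == "H" else "H"
        new_feat = GeneFeature(
            name=event.new_name or src.name, ftype="tRNA", start=ins_at,
            end=ins_at + len(ins_slice), strand=flipped,
            anticodon=src.anticodon)
    L = len(ins_slice)
    g.sequence = g.sequence[:ins_at] + ins_slice + g.sequence[ins_at:]
    for f in g.features:
        if f.start >= ins_at:
            f.start += L
            f.end += L
        elif f.end > ins_at:
            f.end += L  # containing feature (the CR) stretches
    g.features.append(new_feat)
    g.sort_features()
    return g


# ---------------------------------------------------------------------------
# Top-level clade simulation
# ---------------------------------------------------------------------------

def simulate_clade(cfg: SimulationConfig) -> SimulatedClade:
    """Simulate a clade of mitogenomes with full ground truth.

    Deterministic given ``cfg.seed``: a single RNG stream drives root
    assembly, tree generation, branch evolution (pre-order traversal)
    and event injection, in that documented order.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    root, truth = _root_genome(rng, cfg)
    newick = cfg.tree_newick or _random_ultrametric_tree(rng, cfg.n_taxa)
    tree = TreeNode.read(_io.StringIO(newick), convert_underscores=False)
    model = _SiteModel(root, truth, cfg)

    root_arr = np.array(list(root.sequence))
    et = truth["cr"]["etas"]
    root_unit = np.array(list(et["unit"]))

    tip_seqs: dict[str, str] = {}

    def recurse(node, arr: np.ndarray, unit: np.ndarray) -> None:
        for child in node.children:
            a, u = arr.copy(), unit.copy()
            _evolve_branch(a, u, child.length or 0.0, model, cfg, rng)
            if child.is_tip():
                tip_seqs[child.name] = "".join(a)
            else:
                recurse(child, a, u)

    recurse(tree, root_arr, root_unit)

    events_by_taxon: dict[str, list[DuplicationEvent]] = {}
    for ev in cfg.duplication_events:
        events_by_taxon.setdefault(ev.taxon, []).append(ev)

    genomes: list[Mitogenome] = []
    truth["taxa"] = {}
    for name in sorted(tip_seqs):
        g = Mitogenome(id=name, sequence=tip_seqs[name],
                       features=[f for f in root.copy().features])
        taxon_truth: dict[str, Any] = {"events": []}
        for ev in events_by_taxon.get(name, []):
            g.id = name
            before = g.length_bp
            g = inject_duplication(g, ev)
            taxon_truth["events"].append({
                "mode": ev.mode, "source_gene": ev.source_gene,
                "new_name": ev.new_name or ev.source_gene,
                "inserted_bp": g.length_bp - before})
        if cfg.cr_wraps_origin:
            cr = g.get_feature("CR")
            k = cr.start + (cr.end - cr.start) * 2 // 3
            g = _rotate(g, k)
        g.id = name
        genomes.append(g)
        truth["taxa"][name] = taxon_truth

    truth["tree_newick"] = newick
    truth["rates"] = dict(cfg.rates)
    truth["gene_classes"] = {
        n: cfg.gene_classes.get(n, "cds_mid")
        for n, ftype, _ in CANONICAL_GENE_ORDER if ftype == "CDS"}
    truth["seed"] = cfg.seed
    return SimulatedClade(genomes=genomes, truth=truth, tree_newick=newick,
                          config=cfg)


# ---------------------------------------------------------------------------
# Selection-aware coding-pair simulator (for Ka/Ks recovery)
# ---------------------------------------------------------------------------

def simulate_coding_pair(rng: np.random.Generator, n_codons: int = 500,
                         omega: float = 0.25,
                         proposals_per_site: float = 0.5) -> tuple[str, str]:
    """A pair of coding sequences diverged under purifying selection.

    An ancestral stop-free CDS is generated, then each copy accumulates
    substitution proposals (uniform base exchange) totalling
    ``proposals_per_site/2`` per site; synonymous proposals always fix,
    non-synonymous ones fix with probability ``omega``, and stops are
    rejected.  The Ka/Ks of the pair estimates ``omega``.
    """
    from .genetic_code import translate_codon

    anc = random_cds(rng, n_codons)

    def evolve(seq: str) -> str:
        arr = list(seq)
        n_prop = rng.poisson(proposals_per_site / 2 * len(arr))
        for _ in range(n_prop):
            p = int(rng.integers(len(arr)))
            old = arr[p]
            new = "ACGT"[int(rng.integers(4))]
            if new == old:
                continue
            c0 = p - p % 3
            codon = "".join(arr[c0:c0 + 3])
            new_codon = codon[:p - c0] + new + codon[p - c0 + 1:]
            if is_stop(new_codon):
                continue
            if translate_codon(codon) != translate_codon(new_codon):
                if rng.random() > omega:
                    continue
            arr[p] = new
        return "".join(arr)

    return evolve(anc), evolve(anc)
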