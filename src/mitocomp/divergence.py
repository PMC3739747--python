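"""Inter-genome divergence and molecular evolution statistics.

Per-gene nucleotide and amino-acid identity, variable-site fractions,
Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction under the
vertebrate mitochondrial code, a one-way ANOVA comparing region-class
variability, and a desk-scale neighbour-joining topology check on the
concatenated heavy-strand protein genes (ND6, the lone light-strand
CDS, is excluded from the concatenation as its fast evolution invites
homoplasy, but it is retained in the per-gene statistics).
"""

from __future__ import annotations

import io as _io
import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .align import codon_aware_align, multiple_align, pairwise_identity
from .genetic_code import BASES, is_stop, translate_cds, translate_codon
from .model import CANONICAL_GENE_ORDER, Mitogenome

__all__ = [
    "KaKsResult",
    "PhyloCheck",
    "nei_gojobori",
    "synonymous_sites",
    "codon_path_differences",
    "variable_sites",
    "region_variability_anova",
    "gene_pairwise_identities",
    "region_class_identities",
    "divergence_table",
    "concat_and_nj",
    "H_STRAND_PROTEIN_GENES",
]

#: The 12 heavy-strand protein-coding genes used for concatenation.
H_STRAND_PROTEIN_GENES: tuple[str, ...] = tuple(
    name for name, ftype, strand in CANONICAL_GENE_ORDER
    if ftype == "CDS" and strand == "H")


# ---------------------------------------------------------------------------
# Nei–Gojobori Ka/Ks
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Synonymous site count of a sense codon.

    Per position, the fraction of single-base changes (changes to stop
    codons excluded) that preserve the encoded amino acid; summed over
    the three positions.  Non-synonymous sites are 3 minus this.
    """
    aa = translate_codon(codon)
    s = 0.0
    for i in range(3):
        syn = considered = 0
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if is_stop(alt):
                continue
            considered += 1
            if translate_codon(alt) == aa:
                syn += 1
        if considered:
            s += syn / considered
    return s


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/non-synonymous difference counts between two codons,
    averaged over all minimal mutation pathways.

    Pathways passing through a stop codon are excluded; if every
    pathway is blocked, stop intermediates are permitted as a fallback.
    """
    if c1 == c2:
        return 0.0, 0.0

    def paths(cur: str, allow_stop: bool) -> list[tuple[float, float]]:
        diff = [i for i in range(3) if cur[i] != c2[i]]
        if not diff:
            return [(0.0, 0.0)]
        out: list[tuple[float, float]] = []
        for i in diff:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if is_stop(nxt) and nxt != c2 and not allow_stop:
                continue
            step_syn = translate_codon(cur) == translate_codon(nxt)
            for sd, nd in paths(nxt, allow_stop):
                out.append((sd + step_syn, nd + (not step_syn)))
        return out

    results = paths(c1, False) or paths(c1, True)
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction d = -3/4 ln(1 - 4p/3); undefined
    (None) at p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    ka: float | None  # non-synonymous substitutions per non-synonymous site
    ks: float | None  # synonymous substitutions per synonymous site
    ratio: float | None  # Ka/Ks; None when Ks == 0 or a correction fails
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int


def nei_gojobori(a: str, b: str) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks for an aligned pair of coding sequences.

    Site counts are averaged over the two sequences; differences average
    all minimal mutation pathways between differing codons; proportions
    are Jukes–Cantor corrected.  Codon pairs containing N or an
    alignment gap are skipped, as are (with a warning) internal stops.
    Sequences must be equal length; incomplete terminal codons and a
    terminal stop codon are trimmed before counting.
    """
    if len(a) != len(b):
        raise ValueError("nei_gojobori requires equal-length (aligned) sequences")
    a, b = a.upper(), b.upper()
    end = len(a) - len(a) % 3
    sa = sb = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, end, 3):
        c1, c2 = a[i:i + 3], b[i:i + 3]
        if "N" in c1 + c2 or "-" in c1 + c2:
            continue
        stop1, stop2 = is_stop(c1), is_stop(c2)
        if stop1 or stop2:
            if i + 3 < end:
                warnings.warn(f"internal stop codon at codon {i // 3}; skipped")
            continue
        sa += synonymous_sites(c1)
        sb += synonymous_sites(c2)
        n_codons += 1
        d_s, d_n = codon_path_differences(c1, c2)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise ValueError("no comparable codons")
    syn_sites = (sa + sb) / 2.0
    nonsyn_sites = 3.0 * n_codons - syn_sites
    ps = sd / syn_sites if syn_sites > 0 else 0.0
    pn = nd / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, syn_sites=syn_sites,
                      nonsyn_sites=nonsyn_sites, syn_diffs=sd,
                      nonsyn_diffs=nd, n_codons=n_codons)


# ---------------------------------------------------------------------------
# Variable sites and ANOVA
# ---------------------------------------------------------------------------

def variable_sites(aligned: list[str]) -> float:
    """Percent of alignment columns with >=2 distinct non-gap characters.

    All-gap columns are excluded from the denominator.
    """
    if len(aligned) < 2:
        raise ValueError("need at least two sequences")
    if len({len(s) for s in aligned}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    total = variable = 0
    for col in zip(*[s.upper() for s in aligned]):
        chars = {c for c in col if c != "-"}
        if not chars:
            continue
        total += 1
        if len(chars) >= 2:
            variable += 1
    return 100.0 * variable / total if total else 0.0


def region_variability_anova(identity_groups: dict[str, list[float]]
                             ) -> tuple[float, float]:
    """One-way ANOVA across region classes of pairwise identities.

    Returns ``(F, p)``; zero within-group variance with differing means
    yields an infinite F and p = 0.
    """
    groups = [np.asarray(v, dtype=float) for v in identity_groups.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = [g.mean() for g in groups]
    if within == 0:
        if max(means) > min(means):
            return math.inf, 0.0
        return 0.0, 1.0
    from scipy.stats import f_oneway
    res = f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Per-gene and per-region divergence tables
# ---------------------------------------------------------------------------

def _canonical_copy(genome: Mitogenome, name: str):
    """The canonical-position copy of a possibly duplicated gene."""
    copies = genome.get_features(name)
    if not copies:
        return None
    if len(copies) == 1:
        return copies[0]
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    names = [n for n, _, _ in CANONICAL_GENE_ORDER]
    pred = names[names.index(name) - 1] if name in names else None
    for c in copies:
        if pred is not None and feats[feats.index(c) - 1].name == pred:
            return c
    return copies[0]


def _gene_seqs(genomes: list[Mitogenome], name: str) -> dict[str, str]:
    out = {}
    for g in genomes:
        feat = _canonical_copy(g, name)
        if feat is not None:
            out[g.id] = g.feature_sequence(feat)
    return out


def gene_pairwise_identities(genomes: list[Mitogenome], gene: str,
                             alphabet: str = "NT") -> list[float]:
    """All unordered pairwise identities of one gene across genomes."""
    seqs = _gene_seqs(genomes, gene)
    if alphabet.upper() == "AA":
        seqs = {k: translate_cds(s) for k, s in seqs.items()}
    vals = [pairwise_identity(a, b, alphabet=alphabet)
            for a, b in itertools.combinations(seqs.values(), 2)]
    return vals


def region_class_identities(genomes: list[Mitogenome]) -> dict[str, list[float]]:
    """Pairwise nucleotide identities pooled per region class
    (rRNA, tRNA, CDS, CR)."""
    classes: dict[str, list[str]] = {"rRNA": [], "tRNA": [], "CDS": [], "CR": []}
    for name, ftype, _ in CANONICAL_GENE_ORDER:
        if ftype in ("rRNA", "tRNA", "CDS"):
            classes[ftype].append(name)
    classes["CR"] = ["CR"]
    return {cls: [v for gene in genes
                  for v in gene_pairwise_identities(genomes, gene)]
            for cls, genes in classes.items()}


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def divergence_table(genomes: list[Mitogenome],
                     genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene divergence summary over all unordered genome pairs.

    Columns: mean/sd pairwise NT identity, mean/sd AA identity and mean
    Ka/Ks (CDS only; pairs with Ks = 0 are excluded from the mean), and
    the variable-site percentage of the gene's alignment.
    """
    if genes is None:
        genes = [name for name, ftype, _ in CANONICAL_GENE_ORDER
                 if ftype in ("CDS", "rRNA", "tRNA")] + ["CR"]
    ftypes = {name: ftype for name, ftype, _ in CANONICAL_GENE_ORDER}
    rows = []
    for gene in genes:
        seqs = _gene_seqs(genomes, gene)
        if len(seqs) < 2:
            continue
        nt_mean, nt_sd = _mean_sd(
            [pairwise_identity(a, b)
             for a, b in itertools.combinations(seqs.values(), 2)])
        row = {"gene": gene, "ftype": ftypes.get(gene, "noncoding"),
               "nt_identity_mean": nt_mean, "nt_identity_sd": nt_sd,
               "aa_identity_mean": np.nan, "aa_identity_sd": np.nan,
               "kaks_mean": np.nan}
        if ftypes.get(gene) == "CDS":
            aa_mean, aa_sd = _mean_sd(
                [pairwise_identity(a, b, alphabet="AA")
                 for a, b in itertools.combinations(
                     [translate_cds(s) for s in seqs.values()], 2)])
            row["aa_identity_mean"], row["aa_identity_sd"] = aa_mean, aa_sd
            aln = codon_aware_align(seqs)
            ratios = [r.ratio for r in
                      (nei_gojobori(a, b) for a, b in
                       itertools.combinations(aln.values(), 2))
                      if r.ratio is not None]
            if ratios:
                row["kaks_mean"] = float(np.mean(ratios))
            aligned = list(aln.values())
        else:
            aligned = list(multiple_align(seqs).values())
        row["variable_sites_pct"] = variable_sites(aligned)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Concatenated NJ topology check
# ---------------------------------------------------------------------------

@dataclass
class PhyloCheck:
    alignment: dict[str, str]
    distance_matrix: pd.DataFrame
    tree: TreeNode
    newick: str
    rf_distance: float | None
    genes_used: list[str]
    low_support: bool = False


def _p_distance(a: str, b: str) -> float:
    same = diff = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        if x == y:
            same += 1
        else:
            diff += 1
    total = same + diff
    return diff / total if total else 0.0


def concat_and_nj(genomes: list[Mitogenome],
                  reference_newick: str | None = None) -> PhyloCheck:
    """Neighbour-joining recovery check on the concatenated heavy-strand
    protein-coding genes.

    Per-gene codon-aware alignments are concatenated in fixed gene
    order, a p-distance matrix computed, and an NJ tree inferred.  A
    gene missing from any genome is dropped from all, with a warning.
    When a reference topology is supplied the (unrooted) Robinson–Foulds
    distance to it is reported; an RF of 0 means exact recovery.
    """
    if len(genomes) < 4:
        raise ValueError("need at least 4 genomes for an informative topology")
    used: list[str] = []
    parts: dict[str, list[str]] = {g.id: [] for g in genomes}
    for gene in H_STRAND_PROTEIN_GENES:
        seqs = _gene_seqs(genomes, gene)
        if len(seqs) < len(genomes):
            warnings.warn(f"{gene} missing from some genomes; dropped from "
                          "the concatenation")
            continue
        aln = codon_aware_align(seqs)
        for gid, seq in aln.items():
            parts[gid].append(seq)
        used.append(gene)
    if not used:
        raise ValueError("no shared protein-coding genes to concatenate")
    alignment = {gid: "".join(chunks) for gid, chunks in parts.items()}
    ids = [g.id for g in genomes]
    mat = np.zeros((len(ids), len(ids)))
    for i, j in itertools.combinations(range(len(ids)), 2):
        d = _p_distance(alignment[ids[i]], alignment[ids[j]])
        mat[i, j] = mat[j, i] = d
    dm = DistanceMatrix(mat, ids)
    tree = nj(dm)
    rf = None
    low_support = False
    if reference_newick is not None:
        ref = TreeNode.read(_io.StringIO(reference_newick),
                            convert_underscores=False)
        rf = float(tree.compare_rfd(ref))
        # near-zero internal branches (< 5% of the mean pairwise distance)
        # mean the topology carries little signal — star-like data
        internal = [n.length or 0.0 for n in tree.non_tips()]
        mean_d = float(mat[np.triu_indices(len(ids), 1)].mean())
        low_support = bool(internal) and min(internal) < 0.05 * mean_d
    return PhyloCheck(
        alignment=alignment,
        distance_matrix=pd.DataFrame(mat, index=ids, columns=ids),
        tree=tree, newick=str(tree).strip(), rf_distance=rf,
        genes_used=used, low_support=low_support)
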