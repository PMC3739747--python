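"""Pairwise identity, variable sites, Nei–Gojobori Ka/Ks, region ANOVA,
and the neighbour-joining topology check."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import kstest, spearmanr

from mitocomp.align import pairwise_identity
from mitocomp.divergence import (
    codon_path_differences,
    concat_and_nj,
    gene_pairwise_identities,
    nei_gojobori,
    region_class_identities,
    region_variability_anova,
    synonymous_sites,
    variable_sites,
)
from mitocomp.genetic_code import SENSE_CODONS, is_stop, translate_codon
from mitocomp.simulate import SimulationConfig, simulate_clade

# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

def test_identical_sequences_are_100_percent():
    assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0


def test_single_mismatch_identity():
    assert pairwise_identity("ACGT", "ACGA") == 75.0


def test_identity_counts_gap_columns():
    # one insertion: 8 identical columns out of 9 alignment columns
    val = pairwise_identity("ACGTACGT", "ACGTTACGT")
    assert val == pytest.approx(100.0 * 8 / 9)


def test_divergence_matches_jukes_cantor_expectation():
    """Two copies separated by total branch length 0.2 at rate 1 show the
    JC69-expected identity 1/4 + 3/4*exp(-4/3 * 0.2).  Uniform base
    frequencies make the simulator's F81 process exactly JC."""
    expected = 0.25 + 0.75 * math.exp(-4.0 / 3.0 * 0.2)
    uniform = {"A": 0.25, "T": 0.25, "G": 0.25, "C": 0.25}
    rates = {"rRNA": 0.1, "tRNA": 0.1, "cds_slow": 0.1, "cds_mid": 0.1,
             "cds_fast": 0.1, "CR": 0.1}
    vals = []
    for seed in range(30):
        cfg = SimulationConfig(seed=seed, n_taxa=2,
                               tree_newick="(t1:1.0,t2:1.0);",
                               rates=rates, base_freqs=uniform)
        clade = simulate_clade(cfg)
        a, b = (g.extract_gene("16S rRNA") for g in clade.genomes)
        vals.append(sum(x == y for x, y in zip(a, b)) / len(a))
    assert np.mean(vals) == pytest.approx(expected, abs=0.01)


# ---------------------------------------------------------------------------
# variable sites
# ---------------------------------------------------------------------------

def test_identical_alignment_has_no_variable_sites():
    assert variable_sites(["ACGT", "ACGT", "ACGT"]) == 0.0


def test_variable_sites_worked_example():
    # columns A/A/A, A/C/A, G/G/G, T/-/T: one of four is variable
    assert variable_sites(["AAGT", "ACG-", "AAGT"]) == 25.0


def test_all_gap_columns_excluded_from_denominator():
    assert variable_sites(["A-G", "A-G"]) == 0.0
    assert variable_sites(["A-G", "A-T"]) == 50.0


# ---------------------------------------------------------------------------
# Nei–Gojobori
# ---------------------------------------------------------------------------

def _oracle_sites(codon):
    """Independent site counter: direct enumeration of the 9 mutations."""
    s = 0.0
    for pos in range(3):
        syn = considered = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if is_stop(alt):
                continue
            considered += 1
            syn += translate_codon(alt) == translate_codon(codon)
        if considered:
            s += syn / considered
    return s


def _oracle_diffs(c1, c2):
    """Independent difference counter: explicit permutation enumeration
    of mutation orderings, stop-intermediate paths excluded."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order, allow_stop):
        cur, sd, nd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if is_stop(nxt) and nxt != c2 and not allow_stop:
                return None
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    orders = list(itertools.permutations(positions))
    paths = [w for w in (walk(o, False) for o in orders) if w is not None]
    if not paths:
        paths = [walk(o, True) for o in orders]
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def test_sites_and_differences_match_enumeration_oracle():
    """Site and pathway-difference counts agree with independent
    brute-force enumeration over every sense-codon pair to 1e-12."""
    for c in SENSE_CODONS:
        assert synonymous_sites(c) == pytest.approx(_oracle_sites(c), abs=1e-12)
    for c1 in SENSE_CODONS:
        for c2 in SENSE_CODONS:
            sd, nd = codon_path_differences(c1, c2)
            osd, ond = _oracle_diffs(c1, c2)
            assert sd == pytest.approx(osd, abs=1e-12), (c1, c2)
            assert nd == pytest.approx(ond, abs=1e-12), (c1, c2)


def test_identical_pair_has_zero_rates():
    r = nei_gojobori("ATGCCCAAA", "ATGCCCAAA")
    assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None


def test_single_synonymous_difference():
    a = "ATG" + "CTT" * 18 + "GGA"
    b = "ATG" + "CTT" * 18 + "GGG"  # GGA->GGG synonymous (Gly)
    r = nei_gojobori(a, b)
    assert r.ka == 0.0 and r.ks > 0.0
    assert r.syn_diffs == pytest.approx(1.0, abs=1e-12)
    assert r.nonsyn_diffs == pytest.approx(0.0, abs=1e-12)
    # site counts equal the oracle sums averaged over both sequences
    oracle_sites = (sum(map(_oracle_sites, [a[i:i + 3] for i in range(0, len(a), 3)]))
                    + sum(map(_oracle_sites, [b[i:i + 3] for i in range(0, len(b), 3)]))) / 2
    assert r.syn_sites == pytest.approx(oracle_sites, abs=1e-12)


def test_gapped_and_ambiguous_codons_skipped():
    r = nei_gojobori("ATG---AAANNN" + "CCC", "ATGTTTAAAGGG" + "CCC")
    assert r.n_codons == 3  # ATG, AAA, CCC


def test_omega_recovery_from_selection_simulator():
    from mitocomp.simulate import simulate_coding_pair
    vals = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        a, b = simulate_coding_pair(rng, n_codons=500, omega=0.25)
        vals.append(nei_gojobori(a, b).ratio)
    assert 0.15 <= float(np.mean(vals)) <= 0.35


# ---------------------------------------------------------------------------
# region ANOVA
# ---------------------------------------------------------------------------

def test_zero_within_variance_gives_infinite_f():
    f, p = region_variability_anova({"a": [90.0, 90.0], "b": [60.0, 60.0]})
    assert math.isinf(f) and p == 0.0


def test_hand_worked_anova():
    # groups {90,91,89} vs {60,62,58}: SSB=1350 (df 1), SSW=10 (df 4), F=540
    f, p = region_variability_anova({"hi": [90, 91, 89], "lo": [60, 62, 58]})
    assert f == pytest.approx(540.0)
    assert p < 1e-4


def test_null_pvalues_are_uniform():
    """Groups drawn from one normal distribution give p-values uniform
    on [0,1] (Kolmogorov–Smirnov at alpha 0.01 over 500 replicates)."""
    rng = np.random.default_rng(123)
    pvals = []
    for _ in range(500):
        groups = {k: list(rng.normal(80, 5, size=8)) for k in "abc"}
        _, p = region_variability_anova(groups)
        pvals.append(p)
    assert kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# rankings and topology
# ---------------------------------------------------------------------------

def test_gene_divergence_ranking_matches_generating_rates():
    """Genes simulated at rates >=1.5-fold apart rank by divergence in
    the generating order (Spearman rho = 1) across seeds."""
    genes = ["COI", "ND5", "ND6"]  # slow (0.06), mid (0.12), fast (0.24)
    for seed in range(5):
        cfg = SimulationConfig(seed=100 + seed, n_taxa=5)
        clade = simulate_clade(cfg)
        divergence = [100.0 - np.mean(gene_pairwise_identities(clade.genomes, g))
                      for g in genes]
        rho, _ = spearmanr([1, 2, 3], divergence)
        assert rho == 1.0, (seed, divergence)


def test_region_class_ranking(clade4):
    ids = region_class_identities(clade4.genomes)
    means = {k: np.mean(v) for k, v in ids.items()}
    # structural RNAs most conserved, then proteins, CR most divergent
    assert means["rRNA"] > means["CDS"] > means["CR"]
    assert means["tRNA"] > means["CDS"]
    assert abs(means["rRNA"] - means["tRNA"]) < 5.0


def test_nj_recovers_known_topology():
    tree = "((t1:0.3,t2:0.3):0.2,(t3:0.3,t4:0.3):0.2);"
    cfg = SimulationConfig(seed=7, n_taxa=4, tree_newick=tree)
    clade = simulate_clade(cfg)
    check = concat_and_nj(clade.genomes, reference_newick="((t1,t2),(t3,t4));")
    assert check.rf_distance == 0.0
    assert len(check.genes_used) == 12  # heavy-strand proteins; no ND6
    assert "ND6" not in check.genes_used
    assert not check.low_support


def test_star_tree_flagged_low_support():
    star = "((t1:0.5,t2:0.5):0.0,(t3:0.5,t4:0.5):0.0);"
    cfg = SimulationConfig(seed=13, n_taxa=4, tree_newick=star)
    clade = simulate_clade(cfg)
    check = concat_and_nj(clade.genomes, reference_newick="((t1,t2),(t3,t4));")
    assert check.low_support


def test_distance_matrix_symmetric_zero_diagonal(clade4):
    check = concat_and_nj(clade4.genomes)
    m = check.distance_matrix.to_numpy()
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0.0)
    assert set(check.alignment) == {g.id for g in clade4.genomes}
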