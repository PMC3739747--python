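"""Control-region elements, O_L stem-loop, tRNA cloverleaf heuristic,
and supernumerary-tRNA discovery."""

import numpy as np
import pytest

from mitocomp.model import reverse_complement
from mitocomp.simulate import build_trna
from mitocomp.structure import (
    annotate_control_region,
    assess_trna,
    consensus_with_ties,
    derive_consensus,
    detect_novel_trnas,
    find_ol_stemloop,
    find_tandem_repeats,
    global_identity,
    linearized_control_region,
    load_csb_consensus,
    scan_csb,
)

# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def test_exact_tandem_repeat():
    reps = find_tandem_repeats("ACGTACGTACGT", min_period=4)
    assert len(reps) == 1
    r = reps[0]
    assert (r.start, r.period, r.copy_number) == (0, 4, 3.0)
    assert r.unit_sequence == "ACGT"


def test_repeat_units_checked_for_tas_motifs():
    unit = "GG" + "TACAT" + "CCCGG" + "ATGTA" + "GGG"  # 20 bp with TAS + cTAS
    reps = find_tandem_repeats(unit * 3, min_period=5)
    r = max(reps, key=lambda x: x.end - x.start)
    assert r.contains_TAS and r.contains_cTAS and r.hairpin_capable


def test_simulated_etas_tract_recovered(clade4):
    truth = clade4.truth["cr"]["etas"]
    for g in clade4.genomes:
        cr_seq, span = linearized_control_region(g)
        ann = annotate_control_region(cr_seq, span)
        assert ann.etas_repeats, f"{g.id}: no repeat tract found"
        r = ann.etas_repeats[0]
        assert r.start == truth["start"]
        assert r.period == truth["period"]
        assert r.copy_number >= truth["copies"]
        assert r.contains_TAS


# ---------------------------------------------------------------------------
# conserved sequence blocks
# ---------------------------------------------------------------------------

def _plant(rng, consensus, n_flank=120):
    flank = "".join(rng.choice(list("ACGT"), size=n_flank))
    tail = "".join(rng.choice(list("ACGT"), size=n_flank))
    return flank + consensus + tail, n_flank


def test_exact_consensus_found_with_zero_mismatches():
    rng = np.random.default_rng(0)
    csb = load_csb_consensus()
    seq, off = _plant(rng, csb["D"])
    hits = scan_csb(seq, consensus_set={"D": csb["D"]}, tolerance=0.2)
    assert hits[0].start == off and hits[0].mismatches == 0


def test_mutated_csb_e_found_and_contains_gtggg_box():
    rng = np.random.default_rng(1)
    cons = load_csb_consensus()["E"]
    # two substitutions outside the GTGGG identifier box
    mutated = "T" + cons[1] + "A" + cons[3:]
    assert "GTGGG" in mutated
    seq, off = _plant(rng, mutated)
    hits = scan_csb(seq, consensus_set={"E": cons}, tolerance=0.2)
    assert hits and hits[0].start == off and hits[0].mismatches == 2
    assert "GTGGG" in hits[0].matched_sequence


def test_csb2_polyc_consensus_matches_planted_stretch():
    rng = np.random.default_rng(2)
    cons = load_csb_consensus()["2"]
    assert cons == "TAAACCCCCCTACCCCCC"  # poly-C separated by TA
    seq, off = _plant(rng, cons)
    hits = scan_csb(seq, consensus_set={"2": cons}, tolerance=0.0)
    assert hits and hits[0].start == off and hits[0].mismatches == 0


def test_zero_tolerance_scan_equals_naive_substring_search():
    rng = np.random.default_rng(3)
    cons = load_csb_consensus()
    for trial in range(30):
        block = list(cons)[trial % len(cons)]
        target = cons[block]
        present = trial % 2 == 0
        if present:
            seq, _ = _plant(rng, target)
        else:
            seq = "".join(rng.choice(list("ACGT"), size=250))
        hits = scan_csb(seq, consensus_set={block: target}, tolerance=0.0)
        naive = seq.find(target)  # independent oracle: plain substring scan
        if naive == -1:
            assert hits == []
        else:
            assert hits and hits[0].start == naive and hits[0].mismatches == 0


def test_out_of_order_hits_warn():
    cons = load_csb_consensus()
    seq = cons["A"] + "ACGT" * 10 + cons["F"]
    with pytest.warns(UserWarning, match="order"):
        scan_csb(seq, consensus_set={"F": cons["F"], "A": cons["A"]},
                 tolerance=0.0)


# ---------------------------------------------------------------------------
# consensus derivation
# ---------------------------------------------------------------------------

def test_consensus_of_identical_sequences_is_the_sequence():
    assert derive_consensus(["ACGT"] * 3) == {"all": "ACGT"}


def test_majority_column_and_tie_flag():
    # columns: (A,A,G) -> A by majority; (G,T,C) -> three-way tie broken
    # by the fixed base order A<C<G<T and flagged
    cons, ties = consensus_with_ties(["AG", "AT", "GC"])
    assert cons[0] == "A"
    assert cons[1] == "C" and ties == [1]
    cons2, ties2 = consensus_with_ties(["ACA", "ACA", "GTA"])
    assert cons2 == "ACA" and ties2 == []


def test_all_gap_columns_excluded():
    cons, _ = consensus_with_ties(["A-G", "A-G", "A-T"])
    assert cons == "AG"


def test_consensus_recovered_from_mutated_copies():
    """Majority consensus over 10 taxa mutated at 10% per site recovers
    >=19/20 positions of the generating block in >=95% of seeds."""
    target = load_csb_consensus()["F"]
    good = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        seqs = []
        for _ in range(10):
            s = [c if rng.random() > 0.1 else rng.choice(
                [b for b in "ACGT" if b != c]) for c in target]
            seqs.append("".join(s))
        cons, _ = consensus_with_ties(seqs)
        matches = sum(a == b for a, b in zip(cons, target))
        if matches >= len(target) - 1:
            good += 1
    assert good >= 0.95 * n_seeds


# ---------------------------------------------------------------------------
# O_L stem-loop
# ---------------------------------------------------------------------------

def test_constructed_palindrome_stemloop():
    sl = find_ol_stemloop("GGCGC" + "TTTTTT" + "GCGCC")
    assert sl is not None
    assert sl.stem_length_bp == 5
    assert sl.loop_t_fraction == 1.0
    assert sl.stem_mismatches == 0


def test_simulated_ol_recovered(clade4):
    for g in clade4.genomes:
        ol = g.get_feature("OL")
        assert 33 <= ol.length(g.length_bp) <= 43
        asn, cys = g.get_feature("tRNA-Asn"), g.get_feature("tRNA-Cys")
        region = g.sequence[asn.end - 10:cys.start + 10]
        sl = find_ol_stemloop(region)
        assert sl is not None and sl.has_GCCGG_motif
        assert sl.stem_length_bp >= 5
        assert sl.loop_t_fraction >= 0.8
        assert sl.flank_pyrimidine_fraction >= 0.5


def _has_any_hairpin(seq, min_stem=5, max_stem=12, min_loop=3, max_loop=16):
    # independent brute-force check for any qualifying inverted repeat
    for k in range(min_stem, max_stem + 1):
        for l in range(min_loop, max_loop + 1):
            for i in range(0, len(seq) - (2 * k + l) + 1):
                a = seq[i:i + k]
                b = seq[i + k + l:i + 2 * k + l]
                if sum(x != y for x, y in zip(a, reverse_complement(b))) <= 1:
                    return True
    return False


def test_no_hairpin_means_no_stemloop():
    rng = np.random.default_rng(5)
    found = 0
    for _ in range(200):  # rejection-sample hairpin-free 40-mers
        seq = "".join(rng.choice(list("ACGT"), size=40))
        if _has_any_hairpin(seq):
            continue
        found += 1
        assert find_ol_stemloop(seq) is None
        if found >= 5:
            break
    assert found >= 1, "could not sample a hairpin-free negative control"


def test_reported_stems_always_nearly_reverse_complementary(clade4):
    for g in clade4.genomes:
        asn, cys = g.get_feature("tRNA-Asn"), g.get_feature("tRNA-Cys")
        region = g.sequence[asn.end - 10:cys.start + 10]
        sl = find_ol_stemloop(region)
        i, j = sl.span
        k = sl.stem_length_bp
        arm5 = region[i:i + k]
        arm3 = region[j - k:j]
        mism = sum(a != b for a, b in zip(arm5, reverse_complement(arm3)))
        assert mism <= 1


# ---------------------------------------------------------------------------
# tRNA cloverleaf heuristic
# ---------------------------------------------------------------------------

def test_canonical_template_is_cloverleaf():
    rng = np.random.default_rng(7)
    freqs = {"A": 0.29, "T": 0.27, "G": 0.16, "C": 0.28}
    seq = build_trna(rng, "GAT", freqs)
    a = assess_trna(seq)
    assert a.cloverleaf_ok and a.missing_arm == "none"
    assert a.anticodon == "GAU"


def test_d_arm_deletion_gives_truncated_cloverleaf():
    rng = np.random.default_rng(8)
    freqs = {"A": 0.29, "T": 0.27, "G": 0.16, "C": 0.28}
    seq = build_trna(rng, "GCT", freqs, truncated=True)
    a = assess_trna(seq)
    assert a.cloverleaf_ok          # still folds, minus one arm
    assert a.missing_arm == "D-arm"  # the tRNA-Ser(AGY) architecture


def test_anticodon_read_from_planted_loop():
    rng = np.random.default_rng(9)
    freqs = {"A": 0.25, "T": 0.25, "G": 0.25, "C": 0.25}
    # loop = CT + GAT + AT reproduces the worked CTGATAT example
    seq = build_trna(rng, "GAT", freqs)
    a = assess_trna(seq)
    assert a.anticodon == "GAU"


def test_out_of_range_length_reported_not_crashed():
    a = assess_trna("ACGT" * 10)  # 40 nt, below the tRNA size range
    assert not a.cloverleaf_ok and "length" in a.reason


# ---------------------------------------------------------------------------
# supernumerary tRNA discovery
# ---------------------------------------------------------------------------

def test_canonical_genome_has_no_novel_trnas(genomes4):
    assert detect_novel_trnas(genomes4[0]) == []


def test_tandem_duplication_event_detected(clade_events):
    g = next(x for x in clade_events.genomes if x.id == "t1")
    events = detect_novel_trnas(g)
    assert len(events) == 1
    ev = events[0]
    assert ev.event_type == "tandem_duplication_with_anticodon_shift"
    assert ev.source_gene == "tRNA-Val"
    assert ev.extra_gene == "tRNA-Ile"
    assert ev.identity_to_source >= 70.0
    # the copy sits between tRNA-Val and 16S rRNA and reads anticodon AAU
    extra = [f for f in g.get_features("tRNA-Ile")
             if (f.start, f.end) == ev.extra_span][0]
    assert extra.anticodon == "AAU"
    assert assess_trna(g.feature_sequence(extra)).anticodon == "AAU"
    val, rrn = g.get_feature("tRNA-Val"), g.get_feature("16S rRNA")
    assert val.end <= extra.start < rrn.start


def test_cr_duplication_event_detected(clade_events):
    g = next(x for x in clade_events.genomes if x.id == "t2")
    events = detect_novel_trnas(g)
    assert len(events) == 1
    ev = events[0]
    assert ev.event_type == "long_range_duplication_to_CR"
    assert ev.source_gene == "tRNA-Asp"
    assert ev.identity_to_source >= 90.0
    cr = g.get_feature("CR")
    assert cr.start < ev.extra_span[0] and ev.extra_span[1] < cr.end
    extra = [f for f in g.get_features("tRNA-Asp")
             if (f.start, f.end) == ev.extra_span][0]
    assert extra.strand == "L"  # strand-flipped long-range copy


def test_global_identity_range():
    assert global_identity("ACGT", "ACGT") == 100.0
    assert 0.0 <= global_identity("AAAA", "TTTT") <= 100.0
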