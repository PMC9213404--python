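"""Alignment, K3P distances, NJ trees, repeat scanning and subtype calls."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nrltr as N
from nrltr.classify import (DistanceMatrix, align_progressive, classify_perv_type,
                            classify_subtype, detect_repeats, find_u3,
                            k3p_distance, k3p_matrix, nj_tree)
from nrltr.errors import ParameterError, UndefinedDistanceError
from nrltr.util import revcomp

SEQ = st.text(alphabet="ACGT", min_size=8, max_size=40)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# -- progressive alignment --------------------------------------------------


def test_identical_sequences_align_without_gaps():
    msa = align_progressive({"a": "ACGTACGTAA", "b": "ACGTACGTAA"})
    assert msa.rows == ["ACGTACGTAA", "ACGTACGTAA"]


def test_single_deletion_costs_one_gap_column():
    msa = align_progressive({"a": "ACGTACGT", "b": "ACGACGT"})
    assert msa.n_columns == 8
    gappy = msa.row("b")
    assert gappy.count("-") == 1
    matches = sum(x == y for x, y in zip(msa.rows[0], msa.rows[1]))
    assert matches == 7


def test_degap_round_trip_for_random_sequences():
    rng = np.random.default_rng(17)
    seqs = {f"s{i}": _random_seq(rng, int(rng.integers(40, 90)))
            for i in range(21)}
    msa = align_progressive(seqs)
    assert len({len(r) for r in msa.rows}) == 1
    for i, name in enumerate(msa.names):
        assert msa.degapped(i) == seqs[name]


def test_single_sequence_returned_unchanged():
    msa = align_progressive({"only": "ACGT"})
    assert msa.rows == ["ACGT"]


# -- K3P --------------------------------------------------------------------


def test_identical_rows_have_zero_distance():
    assert k3p_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_k3p_closed_form_spot_check():
    # 100 columns: 10 transitions, 5 A<->T / G<->C, 5 A<->C / G<->T
    row_a = "A" * 100
    row_b = "G" * 10 + "T" * 5 + "C" * 5 + "A" * 80
    expected = -0.25 * math.log(0.7 * 0.7 * 0.8)
    assert k3p_distance(row_a, row_b) == pytest.approx(expected, abs=1e-12)


def test_gapped_and_ambiguous_columns_excluded():
    d = k3p_distance("AC-GTN", "ACAGTA")
    assert d == 0.0     # only the four clean identical columns count


def test_zero_comparable_columns_is_an_error():
    with pytest.raises(UndefinedDistanceError):
        k3p_distance("----", "ACGT")


def test_saturated_pairs_report_the_ceiling():
    assert k3p_distance("A" * 50, "G" * 50) == 5.0


@settings(deadline=None, derandomize=True, max_examples=50)
@given(SEQ, SEQ)
def test_k3p_symmetry(a, b):
    n = min(len(a), len(b))
    try:
        assert k3p_distance(a[:n], b[:n]) == k3p_distance(b[:n], a[:n])
    except UndefinedDistanceError:
        pass


def test_k3p_reduces_to_jukes_cantor_in_equal_class_limit():
    """If P = Q = R = p/3 the K3P formula collapses to
    -(3/4) ln(1 - 4p/3); checked algebraically on constructed rows."""
    # 300 columns, p = 0.12 -> 12 of each substitution class
    row_a = "A" * 300
    row_b = "G" * 12 + "T" * 12 + "C" * 12 + "A" * 264
    p = 36 / 300
    assert k3p_distance(row_a, row_b) == pytest.approx(
        -0.75 * math.log(1 - 4 * p / 3), abs=1e-12)


# -- neighbor joining -------------------------------------------------------


def _pdm(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    return {(a.label, b.label): pdm.distance(a, b)
            for i, a in enumerate(taxa) for b in taxa[i + 1:]}


def test_nj_recovers_additive_four_taxon_tree_exactly():
    # generating tree: ((A:1,B:2):3,(C:4,D:5))
    names = ["A", "B", "C", "D"]
    D = np.array([[0, 3, 8, 9],
                  [3, 0, 9, 10],
                  [8, 9, 0, 9],
                  [9, 10, 9, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(names, D, np.zeros((4, 4), bool)))
    dists = _pdm(tree)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            assert dists[(a, b)] == pytest.approx(D[names.index(a),
                                                    names.index(b)], abs=1e-9)
    tree.encode_bipartitions()
    splits = {frozenset(leaf.taxon.label for leaf in e.head_node.leaf_iter())
              for e in tree.preorder_edge_iter() if e.head_node.parent_node}
    assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits


def test_nj_three_taxa_closed_form():
    names = ["x", "y", "z"]
    D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(names, D, np.zeros((3, 3), bool)))
    dists = _pdm(tree)
    assert dists[("x", "y")] == pytest.approx(4)
    assert dists[("x", "z")] == pytest.approx(6)
    assert dists[("y", "z")] == pytest.approx(8)


def test_nj_splits_two_tight_clusters():
    """Two LTR families at small within- and large between-family distance
    must separate across one internal edge."""
    rng = np.random.default_rng(23)
    names = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = names[i][0] == names[j][0]
            D[i, j] = D[j, i] = (0.02 if same else 0.6) + rng.uniform(0, 0.005)
    tree = nj_tree(DistanceMatrix(names, D, np.zeros((n, n), bool)))
    tree.encode_bipartitions()
    splits = {frozenset(leaf.taxon.label for leaf in e.head_node.leaf_iter())
              for e in tree.preorder_edge_iter() if e.head_node.parent_node}
    family_a = frozenset(x for x in names if x.startswith("a"))
    family_b = frozenset(x for x in names if x.startswith("b"))
    assert family_a in splits or family_b in splits


def test_nj_matches_scikit_bio_on_random_additive_matrix():
    """Independent-oracle check: both implementations must recover the same
    topology from an additive matrix derived from a random tree."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(29)
    # random additive matrix via a random tree: ((a,b),(c,d),(e))
    names = list("abcde")
    base = dendropy.Tree.get(data="((a:1.2,b:0.7):0.9,(c:0.4,d:1.5):1.1,e:2.0);",
                             schema="newick")
    pdm = base.phylogenetic_distance_matrix()
    tax = {t.label: t for t in base.taxon_namespace}
    D = np.array([[0 if i == j else pdm.distance(tax[a], tax[b])
                   for j, b in enumerate(names)] for i, a in enumerate(names)])
    mine = nj_tree(DistanceMatrix(names, D, np.zeros_like(D, dtype=bool)))
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj
    theirs = sk_nj(SkDM(D, ids=names))
    ns = dendropy.TaxonNamespace(names)
    t1 = dendropy.Tree.get(data=mine.as_string(schema="newick"),
                           schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=str(theirs).strip(), schema="newick",
                           taxon_namespace=ns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
    assert rf == 0


def test_nj_rejects_degenerate_input():
    with pytest.raises(ParameterError):
        nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)),
                               np.zeros((2, 2), bool)))
    sat = np.ones((3, 3), bool)
    np.fill_diagonal(sat, False)
    with pytest.raises(ParameterError):
        nj_tree(DistanceMatrix(["a", "b", "c"],
                               np.full((3, 3), 5.0) - 5.0 * np.eye(3), sat))


# -- repeat detection -------------------------------------------------------


def test_three_exact_copies_detected():
    rng = np.random.default_rng(31)
    unit = _random_seq(rng, 18)
    seq = _random_seq(rng, 30) + unit * 3 + _random_seq(rng, 30)
    anns = detect_repeats(seq, (18,), min_copies=2, max_unit_mismatch=0)
    assert len(anns) == 1
    ann = anns[0]
    assert (ann.unit_length, ann.start, ann.copy_number) == (18, 30, 3)
    assert ann.consensus == unit
    assert ann.starts == [30, 48, 66]


def test_random_sequences_have_no_exact_arrays():
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        seq = _random_seq(rng, 600)
        assert detect_repeats(seq, (18, 21), min_copies=2,
                              max_unit_mismatch=0) == []


def test_copy_with_two_mismatches_still_counts():
    rng = np.random.default_rng(37)
    unit = _random_seq(rng, 21)
    second = list(unit)
    second[3] = {"A": "C", "C": "G", "G": "T", "T": "A"}[second[3]]
    second[15] = {"A": "C", "C": "G", "G": "T", "T": "A"}[second[15]]
    seq = _random_seq(rng, 25) + unit + "".join(second) + unit + _random_seq(rng, 25)
    anns = detect_repeats(seq, (21,), min_copies=3, max_unit_mismatch=3)
    assert anns and anns[0].copy_number == 3


# -- subtype and PERV typing ------------------------------------------------


def test_all_five_subtypes_round_trip_over_seeds():
    for seed in range(10):
        for label in N.simulate.SUBTYPES:
            build = N.build_ltr(N.subtype_spec(label, seed=seed))
            assert classify_subtype(build.seq).minor == label, (label, seed)


def test_subtype_call_is_reverse_complement_invariant():
    for label in ("A2", "B2"):
        build = N.build_ltr(N.subtype_spec(label, seed=77))
        fwd = classify_subtype(build.seq)
        rev = classify_subtype(revcomp(build.seq))
        assert (fwd.major, fwd.minor) == (rev.major, rev.minor)


def test_ltr_without_any_repeats_is_a1():
    build = N.build_ltr(N.subtype_spec("A1", seed=13))
    call = classify_subtype(build.seq)
    assert (call.major, call.minor) == ("A", "A1")
    assert call.evidence == []


def test_u3_boundary_uses_tata_box():
    build = N.build_ltr(N.subtype_spec("B1", seed=19))
    start, end, found = find_u3(build.seq)
    assert found and (start, end) == build.u3


def test_perv_typing_examples():
    panel = N.make_typed_panel(seed=0)
    rng = np.random.default_rng(41)
    element = _random_seq(rng, 2000) + panel["B"] + _random_seq(rng, 2000)
    call = classify_perv_type(element, panel)
    assert call.perv_type == "B" and call.identity == 1.0
    assert classify_perv_type(_random_seq(rng, 700), panel).perv_type == "unknown"
    with pytest.raises(ParameterError):
        classify_perv_type("ACGT", {})


def test_provirus_types_recovered_through_library(elements):
    panel = N.make_typed_panel(seed=3)
    for ptype in "ABC":
        elem = elements[f"PV_{ptype}"]
        assert classify_perv_type(elem.seq, panel).perv_type == ptype
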