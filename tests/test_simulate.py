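"""Synthetic-data generator: determinism, TSD mechanics, truth alignments."""

import numpy as np
import pytest

import nrltr as N
from nrltr.errors import CoordinateError, ParameterError
from nrltr.simulate import MIN_CLIP_BP
from nrltr.util import gc_fraction, revcomp


# -- reference genomes ------------------------------------------------------


def test_reference_is_deterministic_given_seed():
    spec = N.GenomeSpec(1, 100_000, 0.42, seed=1)
    assert N.generate_reference(spec) == N.generate_reference(spec)


def test_gc_zero_uses_at_alphabet_only():
    ref = N.generate_reference(N.GenomeSpec(1, 10_000, 0.0, seed=2))
    assert set(ref["chr1"]) <= {"A", "T"}


def test_gc_fraction_near_target_on_megabase():
    ref = N.generate_reference(N.GenomeSpec(1, 1_000_000, 0.5, seed=7))
    assert 0.49 <= gc_fraction(ref["chr1"]) <= 0.51


def test_bad_genome_spec_rejected():
    with pytest.raises(ParameterError):
        N.GenomeSpec(1, 500, 0.4, seed=0)


# -- LTR and provirus construction -----------------------------------------


def test_b_type_ltr_contains_both_unit_lengths():
    build = N.build_ltr(N.subtype_spec("B1", seed=1))
    units = {u for u, _, _ in build.repeats}
    assert units == {18, 21}
    u3 = build.seq[build.u3[0]:build.u3[1]]
    for u, start, copies in build.repeats:
        assert start + u * copies <= len(u3)
        unit = build.seq[start:start + u]
        assert build.seq[start:start + u * copies] == unit * copies


def test_a_type_ltr_has_no_full_repeat_arrays():
    build = N.build_ltr(N.subtype_spec("A1", seed=4))
    anns = N.detect_repeats(build.seq, (18, 21), min_copies=2, max_unit_mismatch=3)
    assert anns == []


def test_b3_spec_round_trips_through_classifier():
    build = N.build_ltr(N.subtype_spec("B3", seed=12))
    assert N.classify_subtype(build.seq).minor == "B3"


def test_oversized_repeats_rejected():
    with pytest.raises(ParameterError):
        N.build_ltr(N.LtrSpec(total_length=550,
                              u3_repeat_units=((18, 12), (21, 12)),
                              subtype_label="B3", seed=0))


def test_provirus_length_additivity_and_typing(elements):
    panel = N.make_typed_panel(seed=0)
    ltr = N.build_ltr(N.subtype_spec("B2", seed=5)).seq
    internal = N.make_internal("B", panel, seed=6, length=7000)
    pv = N.build_provirus(ltr, internal, ltr)
    assert len(pv) == 2 * len(ltr) + 7000
    assert N.classify_perv_type(pv, panel).perv_type == "B"
    with pytest.raises(ParameterError):
        N.build_provirus(ltr, "", ltr)


# -- insertions -------------------------------------------------------------


def test_insertion_places_tsd_on_both_sides(elements):
    # a CTAT target site is duplicated around the element
    ref = {"chr1": "A" * 5000 + "CTAT" + "G" * 5000}
    ev = N.InsertionEvent("chr1", 5001, "solo_ltr", "LTR_B1", "+", 4, "CTAT")
    donor = N.insert_elements(ref, [ev], elements)
    elem = elements["LTR_B1"].seq
    expected = "A" * 5000 + "CTAT" + elem + "CTAT" + "G" * 5000
    assert donor.seqs["chr1"] == expected
    t = donor.truth[0]
    assert t.tsd_sequence == "CTAT"
    assert t.expected_reconstruction == "CTAT" + elem + "CTAT"


def test_empty_event_list_returns_reference(elements):
    ref = N.generate_reference(N.GenomeSpec(1, 20_000, 0.4, seed=3))
    donor = N.insert_elements(ref, [], elements)
    assert donor.seqs == ref
    assert donor.truth == []


def test_donor_length_arithmetic(small_world):
    donor = small_world["donor"]
    ref_len = sum(len(s) for s in small_world["reference"].values())
    donor_len = sum(len(s) for s in donor.seqs.values())
    delta = sum((t.donor_elem_end - t.donor_elem_start) + t.tsd_length
                for t in donor.truth)
    assert donor_len == ref_len + delta


def test_tsd_conservation_in_donor(small_world):
    donor = small_world["donor"]
    for t in donor.truth:
        seq = donor.seqs[t.chrom]
        left = seq[t.donor_elem_start - t.tsd_length: t.donor_elem_start]
        right = seq[t.donor_elem_end: t.donor_elem_end + t.tsd_length]
        assert left == right == t.tsd_sequence


def test_event_beyond_chromosome_end_rejected(elements):
    ref = {"chr1": "ACGT" * 5000}
    ev = N.InsertionEvent("chr1", 20_005, "solo_ltr", "LTR_A1", "+", 4, "ACGT")
    with pytest.raises(CoordinateError):
        N.insert_elements(ref, [ev], elements)


def test_overlapping_events_rejected(elements):
    ref = {"chr1": "ACGT" * 5000}
    evs = [N.InsertionEvent("chr1", 1000, "solo_ltr", "LTR_A1", "+", 4, "ACGT"),
           N.InsertionEvent("chr1", 1002, "solo_ltr", "LTR_A1", "+", 4, "GTAC")]
    with pytest.raises(ParameterError):
        N.insert_elements(ref, evs, elements)


def test_minus_orientation_reverse_complements_element_not_tsd(elements):
    ref = {"chr1": "A" * 5000 + "CTAT" + "G" * 5000}
    ev = N.InsertionEvent("chr1", 5001, "solo_ltr", "LTR_A1", "-", 4, "CTAT")
    donor = N.insert_elements(ref, [ev], elements)
    elem = revcomp(elements["LTR_A1"].seq)
    assert donor.seqs["chr1"] == "A" * 5000 + "CTAT" + elem + "CTAT" + "G" * 5000


# -- read simulation --------------------------------------------------------


def test_zero_insertion_donor_yields_only_proper_pairs(elements):
    ref = N.generate_reference(N.GenomeSpec(1, 50_000, 0.42, seed=21))
    donor = N.insert_elements(ref, [], elements)
    reads = N.simulate_reads(donor, N.ReadSimParams(coverage=10, seed=22))
    assert all(p.truth_class == "proper" for p in reads.pairs)


def test_pair_count_matches_requested_coverage(small_world):
    reads = small_world["reads"]
    donor_len = sum(len(s) for s in small_world["donor"].seqs.values())
    expected = 50 * donor_len / (2 * 150)
    assert abs(len(reads.pairs) - expected) / expected < 0.05


def test_soft_clip_boundaries_sit_on_junction_coordinates(small_world):
    truth = small_world["donor"].truth
    left_junctions = {(t.chrom, t.junction_left) for t in truth}
    right_junctions = {(t.chrom, t.junction_right) for t in truth}
    n_clipped = 0
    for pair in small_world["reads"].pairs:
        for r in (pair.r1, pair.r2):
            if not r.is_mapped:
                continue
            if r.clip_right >= MIN_CLIP_BP:
                assert (r.chrom, r.end) in left_junctions
                n_clipped += 1
            if r.clip_left >= MIN_CLIP_BP:
                assert (r.chrom, r.pos) in right_junctions
                n_clipped += 1
    assert n_clipped > 0


def test_no_proper_pair_overlaps_a_junction(small_world):
    truth = small_world["donor"].truth
    junctions = [(t.chrom, t.junction_left, t.junction_right) for t in truth]
    for pair in small_world["reads"].pairs:
        if pair.truth_class != "proper":
            continue
        for r in (pair.r1, pair.r2):
            for chrom, jl, jr in junctions:
                if r.chrom == chrom:
                    # a proper read may touch the duplicated target site but
                    # never extends across the element boundary
                    assert not (r.pos <= jl and r.end > jl and r.clip_right == 0
                                and r.pos < jr <= r.end and r.clip_left == 0)


def test_fastq_and_sam_outputs_are_byte_identical_across_runs(tmp_path, elements):
    ref = N.generate_reference(N.GenomeSpec(1, 30_000, 0.42, seed=31))
    events = N.plan_insertions(ref, elements, n=1, seed=32, edge_margin=1500)
    donor = N.insert_elements(ref, events, elements)
    blobs = []
    for run in range(2):
        reads = N.simulate_reads(donor, N.ReadSimParams(coverage=8, seed=33))
        f1, f2, sam = (tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq",
                       tmp_path / f"{run}.sam")
        reads.write_fastq(f1, f2)
        reads.write_sam(sam)
        blobs.append((f1.read_bytes(), f2.read_bytes(), sam.read_bytes()))
    assert blobs[0] == blobs[1]


def test_truth_table_round_trip(tmp_path, small_world):
    truth = small_world["donor"].truth
    p = tmp_path / "truth.tsv"
    N.write_truth(truth, p)
    back = N.read_truth(p)
    assert [(t.chrom, t.position, t.element_id, t.tsd_sequence, t.expected_ltr)
            for t in back] == \
           [(t.chrom, t.position, t.element_id, t.tsd_sequence, t.expected_ltr)
            for t in sorted(truth, key=lambda t: (t.chrom, t.position))]


def test_invalid_read_sim_params_rejected():
    with pytest.raises(ParameterError):
        N.ReadSimParams(read_length=150, fragment_mean=100)
    with pytest.raises(ParameterError):
        N.ReadSimParams(coverage=0)
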