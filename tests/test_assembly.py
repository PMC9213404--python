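"""Greedy OLC assembly, junction analysis and LTR reconstruction."""

import random

import numpy as np
import pytest

import nrltr as N
from nrltr.assembly import analyze_junction, assemble, extract_junction_reads
from nrltr.errors import ParameterError
from nrltr.formats import AlignedRead, CallRecord
from nrltr.util import revcomp


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# -- assemble ---------------------------------------------------------------


def test_two_reads_with_sixty_base_overlap_merge():
    rng = np.random.default_rng(1)
    region = _random_seq(rng, 240)
    a, b = region[:150], region[90:240]
    contigs = assemble([a, b], min_overlap=40)
    assert len(contigs) == 1
    assert contigs[0].sequence in (region, revcomp(region))
    assert contigs[0].n_reads == 2


def test_overlap_below_minimum_stays_split():
    rng = np.random.default_rng(2)
    region = _random_seq(rng, 261)
    a, b = region[:150], region[111:261]        # 39-base overlap
    contigs = assemble([a, b], min_overlap=40)
    assert len(contigs) == 2


def test_reverse_complement_reads_are_used():
    rng = np.random.default_rng(3)
    region = _random_seq(rng, 240)
    contigs = assemble([region[:150], revcomp(region[90:240])], min_overlap=40)
    assert len(contigs) == 1
    assert contigs[0].sequence in (region, revcomp(region))


def test_tiling_reads_reconstruct_region_exactly():
    rng = np.random.default_rng(4)
    region = _random_seq(rng, 700)
    reads = [region[i:i + 150] for i in range(0, 550, 10)] + [region[550:700]]
    contigs = assemble(reads)
    assert contigs[0].sequence in (region, revcomp(region))
    assert contigs[0].coverage.min() >= 1


def test_assembly_is_input_order_invariant():
    rng = np.random.default_rng(5)
    region = _random_seq(rng, 600)
    reads = [region[i:i + 150] for i in range(0, 450, 17)]
    baseline = sorted(c.sequence for c in assemble(reads))
    shuffler = random.Random(99)
    for _ in range(3):
        shuffled = reads[:]
        shuffler.shuffle(shuffled)
        assert sorted(c.sequence for c in assemble(shuffled)) == baseline


def test_substitution_errors_resolved_by_majority_consensus():
    rng = np.random.default_rng(6)
    region = _random_seq(rng, 400)
    reads = [region[i:i + 150] for i in range(0, 250, 10)]
    bad = list(reads[3])
    bad[75] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[75]]
    reads[3] = "".join(bad)
    contigs = assemble(reads, min_overlap=40, min_overlap_identity=0.9)
    expected = region[:390]          # reads tile positions 0..390
    assert contigs[0].sequence in (expected, revcomp(expected))


def test_empty_read_set_rejected():
    with pytest.raises(ParameterError):
        assemble([])


# -- junction read extraction ----------------------------------------------


def _mapped(pos, cigar="150M", flag=0x1 | 0x40, chrom="chr1"):
    return AlignedRead("q", flag, chrom, pos, 60, cigar, "A" * 150)


def test_window_rule_for_junction_reads():
    center = 10_000
    inside = _mapped(center - 180)           # ends 30 bp left of center
    outside = _mapped(center - 301)          # ends 151 bp away
    mate = _mapped(center + 10, flag=0x1 | 0x80 | 0x10)
    s5, s3 = extract_junction_reads([(inside, mate), (outside, mate)],
                                    "chr1", center, window=150)
    assert inside.seq in s5
    # the out-of-window read is excluded; the mapped downstream mate lands in
    # the 3' set once per pair it appears in
    assert len(s5) == 1 and len(s3) == 2


def test_clip_side_routing():
    center = 10_000
    right_clipped = AlignedRead("a", 0x1, "chr1", center - 100, 60, "104M46S",
                                "C" * 150)
    left_clipped = AlignedRead("b", 0x1, "chr1", center, 60, "40S110M",
                               "G" * 150)
    mate = _mapped(center + 400)
    s5, s3 = extract_junction_reads([(right_clipped, mate),
                                     (left_clipped, mate)],
                                    "chr1", center, window=150)
    assert right_clipped.seq in s5 and left_clipped.seq in s3


def test_junction_spanning_truth_reads_are_captured(small_world):
    donor = small_world["donor"]
    pairs = [(p.r1, p.r2) for p in small_world["reads"].pairs]
    for t in donor.truth:
        center = t.position + t.tsd_length // 2
        s5, s3 = extract_junction_reads(pairs, t.chrom, center)
        assert len(s5) >= 2 and len(s3) >= 2


# -- junction analysis ------------------------------------------------------


def test_ref_plus_ltr_contig_is_a_5p_junction(library):
    rng = np.random.default_rng(7)
    ref = {"chr1": _random_seq(rng, 4000)}
    elem_name, elem_seq = sorted(library.items())[0]
    contig_seq = ref["chr1"][1850:2000] + elem_seq[:300]
    call = CallRecord(chrom="chr1", breakpoint_pos=2000, support_5p=10,
                      support_3p=10, filter_level=7)
    from nrltr.assembly import Contig
    j = analyze_junction(Contig.from_seq(contig_seq), ref, call, library)
    assert j is not None
    assert j.junction_side == "5p"
    assert j.nonref_element == elem_name
    assert j.nonref_identity == 1.0
    assert j.nonref_seq == elem_seq[:300]


def test_pure_reference_contig_yields_no_junction(library):
    rng = np.random.default_rng(8)
    ref = {"chr1": _random_seq(rng, 4000)}
    call = CallRecord(chrom="chr1", breakpoint_pos=2000, support_5p=10,
                      support_3p=10, filter_level=7)
    from nrltr.assembly import Contig
    j = analyze_junction(Contig.from_seq(ref["chr1"][1700:2100]), ref, call,
                         library)
    assert j is None


# -- reconstruction ---------------------------------------------------------


def test_planted_insertions_reconstructed_exactly(pipeline_result, small_world):
    truth = {(t.chrom, t.position): t for t in small_world["donor"].truth}
    assert len(pipeline_result.loci) == len(truth)
    for locus in pipeline_result.loci:
        rec = locus.reconstruction
        assert rec is not None and rec.completeness == "both"
        t = truth[(locus.call.chrom, locus.call.tsd_start)]
        assert rec.sequence == t.expected_reconstruction
        assert rec.overlap_mismatches == 0
        assert rec.length_with_tsd == len(t.expected_reconstruction)


def test_reconstruction_never_claims_both_without_two_tsds(pipeline_result):
    for locus in pipeline_result.loci:
        rec = locus.reconstruction
        if rec is not None and rec.completeness == "both":
            assert rec.tsd5 is not None and rec.tsd3 is not None


def test_one_sided_junction_gives_partial_completeness(pipeline_result,
                                                       small_world, library):
    from nrltr.assembly import reconstruct_ltr
    locus = pipeline_result.loci[0]
    rec = reconstruct_ltr(locus.call, locus.junction_5p, None, locus.tsd)
    assert rec.completeness == "5p_only"
    rec3 = reconstruct_ltr(locus.call, None, locus.junction_3p, locus.tsd)
    assert rec3.completeness == "3p_only"


def test_provirus_ltr_copy_mutation_surfaces_as_overlap_mismatch():
    """A provirus whose 3' LTR carries one substitution relative to its 5'
    LTR reconstructs with overlap_mismatches >= 1 (the two junction contigs
    disagree inside their merged overlap)."""
    elements = N.make_element_library(seed=3, ltr3_mutation_for="PV_B")
    lib = N.ltr_library(elements)
    ref = N.generate_reference(N.GenomeSpec(1, 60_000, 0.42, seed=61))
    ev = N.InsertionEvent("chr1", 30_000, "provirus", "PV_B", "+", 4,
                          ref["chr1"][29_999:30_003])
    donor = N.insert_elements(ref, [ev], elements)
    reads = N.simulate_reads(donor, N.ReadSimParams(coverage=50, seed=62))
    res = N.run_pipeline(reads.pairs, ref, lib)
    assert len(res.loci) == 1
    rec = res.loci[0].reconstruction
    assert rec is not None and rec.completeness == "both"
    assert rec.overlap_mismatches >= 1
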