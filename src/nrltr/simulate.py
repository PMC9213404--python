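"""Synthetic genomes, LTR/provirus elements, insertions and paired-end reads.

Everything the pipeline consumes can be generated here with no external data:
a random reference genome, an element library whose LTRs carry controlled U3
tandem-repeat structure (subtypes A1/A2/B1/B2/B3), donor genomes with
TSD-flanked insertions, and error-free or error-bearing 150-bp paired-end
reads together with their truth alignments against the *original* reference
(emulating what a read aligner would report, so no aligner is needed).

Coordinates: file outputs and truth records are 1-based inclusive (SAM
convention); internal arithmetic is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from bisect import bisect_right
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import CoordinateError, ParameterError
from .formats import (AlignedRead, FLAG_MATE_REVERSE, FLAG_MATE_UNMAPPED,
                      FLAG_PAIRED, FLAG_PROPER, FLAG_READ1, FLAG_READ2,
                      FLAG_REVERSE, FLAG_UNMAPPED, write_fastq_pair, write_sam)
from .util import random_seq, revcomp

SUBTYPES = ("A1", "A2", "B1", "B2", "B3")

#: a truth read must keep at least this many aligned bases to count as mapped
MIN_ANCHOR_BP = 20

#: minimal soft clip that the simulator (and discovery) treats as informative
MIN_CLIP_BP = 10

_TATA_RE = re.compile("TATA[AT]A")


# ==========================================================================
# Reference genomes
# ==========================================================================


@dataclass(slots=True)
class GenomeSpec:
    """Parameters for a random reference genome."""

    n_chromosomes: int = 1
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.chrom_length < 10_000:
            raise ParameterError("need >=1 chromosome of >=10 kb")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ParameterError("gc_fraction must be within [0, 1]")


def generate_reference(spec: GenomeSpec) -> dict[str, str]:
    """Deterministic random genome: ``{"chr1": seq, ...}`` over {A,C,G,T}."""
    rng = np.random.default_rng(spec.seed)
    return {f"chr{i + 1}": random_seq(rng, spec.chrom_length, spec.gc_fraction)
            for i in range(spec.n_chromosomes)}


# ==========================================================================
# LTR and provirus construction
# ==========================================================================


@dataclass(slots=True)
class LtrSpec:
    """Blueprint for a single LTR with controlled U3 repeat structure.

    ``u3_repeat_units`` lists ``(unit_length, copies)`` tandem arrays to plant
    inside U3 (unit lengths 18 or 21, the promoter/enhancer repeat periods of
    the B-type elements).  ``sub_repeat`` optionally plants a shorter
    (8-15 bp) array, the hallmark distinguishing subtype A2 from A1.
    """

    total_length: int = 600
    u3_repeat_units: Sequence[tuple[int, int]] = ()
    subtype_label: str = "A1"
    seed: int = 0
    sub_repeat: tuple[int, int] | None = None  # (unit_length, copies)

    def __post_init__(self):
        if not 550 <= self.total_length <= 760:
            raise ParameterError("total_length outside [550, 760]")
        if self.subtype_label not in SUBTYPES:
            raise ParameterError(f"unknown subtype label {self.subtype_label!r}")
        for u, c in self.u3_repeat_units:
            if u not in (18, 21) or c < 0:
                raise ParameterError("repeat units must be 18 or 21 bp with copies >= 0")
        if self.subtype_label.startswith("B"):
            lens = {u for u, c in self.u3_repeat_units if c >= 1}
            if not {18, 21} <= lens:
                raise ParameterError("B-labelled specs need >=1 copy of an 18-bp "
                                     "and a 21-bp unit")
        else:
            if any(c >= 1 for _, c in self.u3_repeat_units):
                raise ParameterError("A-labelled specs must have 0 copies of "
                                     "18/21-bp units")


# layout constants: U3 | TATA box | R | U5
_TATA = "TATAAA"
_R_LEN = 60
_U5_LEN = 75


@dataclass(slots=True)
class LtrBuild:
    """A built LTR with its annotation (0-based half-open intervals)."""

    seq: str
    u3: tuple[int, int]
    r: tuple[int, int]
    u5: tuple[int, int]
    repeats: list[tuple[int, int, int]]        # (unit_length, start, copies)
    sub_repeat: tuple[int, int, int] | None    # (unit_length, start, copies)
    spec: LtrSpec


def subtype_spec(label: str, seed: int = 0, total_length: int = 600) -> LtrSpec:
    """Canonical spec for each of the five subtypes.

    Copy numbers place B1/B2/B3 in the default classifier tiers (total
    18+21-bp copies <=4 / 5-6 / >=7); A2 carries a 12-bp sub-repeat array.
    """
    units = {"A1": (), "A2": (),
             "B1": ((18, 2), (21, 2)),
             "B2": ((18, 3), (21, 3)),
             "B3": ((18, 4), (21, 4))}[label]
    sub = (12, 3) if label == "A2" else None
    return LtrSpec(total_length=total_length, u3_repeat_units=units,
                   subtype_label=label, seed=seed, sub_repeat=sub)


def _scrub_motif(seq: list[str], pattern: re.Pattern, protected: set[int]) -> None:
    """Destroy every match of ``pattern`` whose span is not protected."""
    for _ in range(200):
        m = None
        for cand in pattern.finditer("".join(seq)):
            if not any(p in protected for p in range(cand.start(), cand.end())):
                m = cand
                break
        if m is None:
            return
        i = m.start() + 2
        seq[i] = "C" if seq[i] != "C" else "G"
    raise AssertionError("motif scrubbing did not converge")


def _scrub_arrays(seq: list[str], unit_lengths: Iterable[int], protected: set[int],
                  max_unit_mismatch, rng: np.random.Generator) -> None:
    """Mutate chance tandem arrays (outside protected spans) until none remain."""
    from .classify import detect_repeats  # local import: no circular module load

    for _ in range(200):
        hits = []
        s = "".join(seq)
        for ann in detect_repeats(s, unit_lengths=tuple(unit_lengths),
                                  min_copies=2,
                                  max_unit_mismatch=max_unit_mismatch):
            span = range(ann.start, ann.start + ann.unit_length * ann.copy_number)
            if not any(p in protected for p in span):
                hits.append(ann)
        if not hits:
            return
        ann = hits[0]
        # break the array by mutating one base in its second unit copy
        i = ann.start + ann.unit_length + ann.unit_length // 2
        seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
    raise AssertionError("array scrubbing did not converge")


def build_ltr(spec: LtrSpec) -> LtrBuild:
    """Build an LTR whose structure matches its subtype label by construction.

    The returned annotation places every requested repeat copy as a tandem
    block near the start of U3; chance motifs that would confuse the
    classifier (stray TATA boxes, accidental tandem arrays on A-type
    elements) are scrubbed deterministically.
    """
    rng = np.random.default_rng(spec.seed)
    u3_len = spec.total_length - len(_TATA) - _R_LEN - _U5_LEN
    arrays = [(u, c) for u, c in spec.u3_repeat_units if c >= 1]
    span_needed = sum(u * c for u, c in arrays) + 5 * max(0, len(arrays) - 1)
    if spec.sub_repeat:
        span_needed += spec.sub_repeat[0] * spec.sub_repeat[1] + 5
    left_pad = 20
    if left_pad + span_needed + 10 > u3_len:
        raise ParameterError("requested repeats do not fit inside U3")

    parts: list[str] = [random_seq(rng, left_pad, 0.45)]
    pos = left_pad
    repeats: list[tuple[int, int, int]] = []
    protected: set[int] = set()
    for u, c in arrays:
        unit = random_seq(rng, u, 0.5)
        parts.append(unit * c)
        repeats.append((u, pos, c))
        protected.update(range(pos, pos + u * c))
        pos += u * c
        spacer = random_seq(rng, 5, 0.45)
        parts.append(spacer)
        pos += 5
    sub_ann = None
    if spec.sub_repeat:
        u, c = spec.sub_repeat
        unit = random_seq(rng, u, 0.5)
        parts.append(unit * c)
        sub_ann = (u, pos, c)
        protected.update(range(pos, pos + u * c))
        pos += u * c
        parts.append(random_seq(rng, 5, 0.45))
        pos += 5
    parts.append(random_seq(rng, u3_len - pos, 0.45))
    u3 = "".join(parts)
    assert len(u3) == u3_len

    seq = list(u3 + _TATA + random_seq(rng, _R_LEN, 0.5) + random_seq(rng, _U5_LEN, 0.5))
    tata_span = range(u3_len, u3_len + len(_TATA))
    protected.update(tata_span)

    # keep exactly one TATA box, and keep A-type elements free of arrays the
    # classifier would count (18/21-bp everywhere; sub-repeats for A types)
    _scrub_motif(seq, _TATA_RE, protected)
    if spec.subtype_label.startswith("A"):
        _scrub_arrays(seq, (18, 21), protected, max_unit_mismatch=3, rng=rng)
        _scrub_arrays(seq, tuple(range(8, 16)), protected,
                      max_unit_mismatch=1, rng=rng)
        _scrub_motif(seq, _TATA_RE, protected)

    out = "".join(seq)
    return LtrBuild(seq=out,
                    u3=(0, u3_len),
                    r=(u3_len + len(_TATA), u3_len + len(_TATA) + _R_LEN),
                    u5=(spec.total_length - _U5_LEN, spec.total_length),
                    repeats=repeats, sub_repeat=sub_ann, spec=spec)


def make_typed_panel(seed: int = 0, length: int = 600) -> dict[str, str]:
    """Synthetic pol-region marker panel, one sequence per PERV type (A/B/C).

    Stand-in for the typed reference panel a user would supply; the three
    markers are mutually unrelated random sequences so best-hit typing is
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    return {t: random_seq(rng, length, 0.5) for t in ("A", "B", "C")}


def make_internal(perv_type: str, panel: dict[str, str], seed: int = 0,
                  length: int = 7000) -> str:
    """Synthetic provirus internal region carrying the typed pol marker."""
    if perv_type not in panel:
        raise ParameterError(f"panel has no type {perv_type!r}")
    marker = panel[perv_type]
    if length < len(marker) + 200:
        raise ParameterError("internal region too short for the pol marker")
    rng = np.random.default_rng(seed)
    pad = length - len(marker)
    left = pad // 2
    return random_seq(rng, left, 0.45) + marker + random_seq(rng, pad - left, 0.45)


def build_provirus(ltr5: str, internal: str, ltr3: str) -> str:
    """Full provirus: 5' LTR + internal (gag/pol/env) region + 3' LTR."""
    if not ltr5 or not internal or not ltr3:
        raise ParameterError("provirus components must be non-empty")
    return ltr5 + internal + ltr3


def mutate_sequence(seq: str, rate: float, seed: int = 0,
                    protect: Iterable[tuple[int, int]] = ()) -> str:
    """Random substitutions at ``rate`` per base, sparing protected spans."""
    rng = np.random.default_rng(seed)
    chars = list(seq)
    shielded = set()
    for a, b in protect:
        shielded.update(range(a, b))
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        if int(i) in shielded:
            continue
        alt = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alt[rng.integers(3)]
    return "".join(chars)


# ==========================================================================
# Element library
# ==========================================================================


@dataclass(slots=True)
class Element:
    """A library element available for insertion."""

    id: str
    kind: str                 # "solo_ltr" | "provirus"
    seq: str
    subtype: str              # LTR subtype label
    perv_type: str | None     # A/B/C for proviruses, None for solo LTRs
    ltr: LtrBuild


def make_element_library(seed: int = 0, internal_length: int = 7000,
                         ltr3_mutation_for: str | None = None) -> dict[str, Element]:
    """Five solo-LTR elements (one per subtype) plus three typed proviruses.

    ``ltr3_mutation_for`` optionally plants a single substitution in the 3'
    LTR copy of that provirus, emulating post-insertion divergence between
    the two LTR copies of one element.
    """
    panel = make_typed_panel(seed)
    elements: dict[str, Element] = {}
    for i, label in enumerate(SUBTYPES):
        build = build_ltr(subtype_spec(label, seed=(seed * 9973 + i) % 2**31))
        elements[f"LTR_{label}"] = Element(f"LTR_{label}", "solo_ltr", build.seq,
                                           label, None, build)
    for j, (ptype, sub) in enumerate([("A", "A2"), ("B", "B2"), ("C", "B1")]):
        build = build_ltr(subtype_spec(sub, seed=(seed * 9973 + 100 + j) % 2**31))
        internal = make_internal(ptype, panel,
                                 seed=(seed * 9973 + 200 + j) % 2**31,
                                 length=internal_length)
        ltr3 = build.seq
        pid = f"PV_{ptype}"
        if ltr3_mutation_for == pid:
            mid = len(ltr3) // 2
            ltr3 = ltr3[:mid] + ("A" if ltr3[mid] != "A" else "G") + ltr3[mid + 1:]
        elements[pid] = Element(pid, "provirus",
                                build_provirus(build.seq, internal, ltr3),
                                sub, ptype, build)
    return elements


def ltr_library(elements: dict[str, Element]) -> dict[str, str]:
    """The LTR sequences of every element — the discovery-stage library."""
    return {f"{e.id}_LTR": e.ltr.seq for e in elements.values()}


def make_ltr_cohort(n_a: int = 10, n_b: int = 11, seed: int = 0,
                    divergence: float = 0.03) -> tuple[dict[str, str], dict[str, str]]:
    """A cohort of related LTR sequences from two families (A-like, B-like).

    Members descend from one A-type and one B-type ancestor by random
    substitutions (repeat arrays and the TATA box are spared so the family
    label stays well defined).  Returns ``(sequences, true_major_labels)``.
    """
    anc_a = build_ltr(subtype_spec("A1", seed=seed % 2**31))
    anc_b = build_ltr(subtype_spec("B2", seed=(seed + 7) % 2**31))
    protect_b = [(s, s + u * c) for u, s, c in anc_b.repeats]
    protect_b.append((anc_b.u3[1], anc_b.u3[1] + len(_TATA)))
    protect_a = [(anc_a.u3[1], anc_a.u3[1] + len(_TATA))]
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for i in range(n_a):
        name = f"ltrA_{i + 1:02d}"
        seqs[name] = mutate_sequence(anc_a.seq, divergence,
                                     seed=(seed + 1000 + i) % 2**31,
                                     protect=protect_a)
        labels[name] = "A"
    for i in range(n_b):
        name = f"ltrB_{i + 1:02d}"
        seqs[name] = mutate_sequence(anc_b.seq, divergence,
                                     seed=(seed + 2000 + i) % 2**31,
                                     protect=protect_b)
        labels[name] = "B"
    return seqs, labels


# ==========================================================================
# Insertions
# ==========================================================================


@dataclass(slots=True)
class InsertionEvent:
    """A planted insertion; ``position`` is the 1-based first base of the
    duplicated target site on the reference."""

    chrom: str
    position: int
    element_kind: str         # "solo_ltr" | "provirus"
    element_id: str
    orientation: str          # "+" | "-"
    tsd_length: int
    tsd_sequence: str = ""

    def __post_init__(self):
        if self.tsd_length not in (4, 5):
            raise ParameterError("tsd_length must be 4 or 5")
        if self.orientation not in "+-":
            raise ParameterError("orientation must be '+' or '-'")


@dataclass(slots=True)
class TruthRecord:
    """Ground truth for one planted insertion, with donor coordinates."""

    chrom: str
    position: int             # 1-based first base of target site (reference)
    element_kind: str
    element_id: str
    orientation: str
    tsd_length: int
    tsd_sequence: str
    subtype: str
    perv_type: str
    donor_elem_start: int     # 0-based half-open element span in the donor
    donor_elem_end: int
    expected_ltr: str         # LTR sequence as oriented in the donor

    @property
    def junction_left(self) -> int:
        """1-based reference position of the last base before the element."""
        return self.position + self.tsd_length - 1

    @property
    def junction_right(self) -> int:
        """1-based reference position of the first base after the element."""
        return self.position

    @property
    def expected_reconstruction(self) -> str:
        """TSD-to-TSD sequence a perfect reconstruction reports."""
        return self.tsd_sequence + self.expected_ltr + self.tsd_sequence


_TRUTH_COLUMNS = ["chrom", "pos", "kind", "element_id", "orientation",
                  "tsd_len", "tsd_seq", "subtype", "perv_type",
                  "donor_start", "donor_end", "expected_ltr"]


def write_truth(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# nrltr truth table; pos 1-based\n")
        fh.write("#" + "\t".join(_TRUTH_COLUMNS) + "\n")
        for t in sorted(truth, key=lambda t: (t.chrom, t.position)):
            fh.write("\t".join(map(str, [
                t.chrom, t.position, t.element_kind, t.element_id,
                t.orientation, t.tsd_length, t.tsd_sequence, t.subtype,
                t.perv_type or ".", t.donor_elem_start, t.donor_elem_end,
                t.expected_ltr])) + "\n")


def read_truth(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            out.append(TruthRecord(p[0], int(p[1]), p[2], p[3], p[4], int(p[5]),
                                   p[6], p[7], "" if p[8] == "." else p[8],
                                   int(p[9]), int(p[10]), p[11]))
    return out


def plan_insertions(reference: dict[str, str], elements: dict[str, Element],
                    n: int, seed: int = 0, min_spacing: int = 2000,
                    edge_margin: int = 2000,
                    tsd_lengths: Sequence[int] = (4, 5)) -> list[InsertionEvent]:
    """Place ``n`` insertions cycling through the element library.

    Positions are drawn uniformly, kept >= ``min_spacing`` apart and away
    from chromosome ends; TSD lengths alternate through ``tsd_lengths``;
    orientations are random.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(reference)
    ids = sorted(elements)
    events: list[InsertionEvent] = []
    taken: dict[str, list[int]] = {c: [] for c in chroms}
    attempts = 0
    while len(events) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise ParameterError("could not place insertions with the "
                                 "requested spacing")
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = len(reference[chrom])
        if L < 2 * edge_margin + min_spacing:
            continue
        pos = int(rng.integers(edge_margin, L - edge_margin))
        if any(abs(pos - p) < min_spacing for p in taken[chrom]):
            continue
        eid = ids[len(events) % len(ids)]
        tsd_len = int(tsd_lengths[len(events) % len(tsd_lengths)])
        orientation = "+" if rng.random() < 0.5 else "-"
        events.append(InsertionEvent(
            chrom=chrom, position=pos, element_kind=elements[eid].kind,
            element_id=eid, orientation=orientation, tsd_length=tsd_len,
            tsd_sequence=reference[chrom][pos - 1: pos - 1 + tsd_len]))
        taken[chrom].append(pos)
    events.sort(key=lambda e: (e.chrom, e.position))
    return events


@dataclass(slots=True)
class _Block:
    donor_start: int
    donor_end: int
    kind: str               # "ref" | "elem"
    ref_start: int = 0      # 0-based reference offset of donor_start (ref blocks)
    truth: TruthRecord | None = None


@dataclass
class DonorGenome:
    """A donor genome with its block map and insertion ground truth."""

    seqs: dict[str, str]
    blocks: dict[str, list[_Block]]
    truth: list[TruthRecord]
    reference_lengths: dict[str, int]


def insert_elements(reference: dict[str, str], events: Sequence[InsertionEvent],
                    elements: dict[str, Element]) -> DonorGenome:
    """Apply insertion events: each element lands between two copies of its
    4-5 bp target site (the TSD), i.e. ``ref[..pos+tsd-1] + element + ref[pos..]``.
    """
    by_chrom: dict[str, list[InsertionEvent]] = {}
    for e in events:
        if e.chrom not in reference:
            raise CoordinateError(f"unknown chromosome {e.chrom!r}")
        L = len(reference[e.chrom])
        if not 1 <= e.position <= L - e.tsd_length + 1:
            raise CoordinateError(f"event at {e.chrom}:{e.position} beyond "
                                  f"chromosome end ({L} bp)")
        by_chrom.setdefault(e.chrom, []).append(e)
    donor: dict[str, str] = {}
    blocks: dict[str, list[_Block]] = {}
    truth: list[TruthRecord] = []
    for chrom, ref in reference.items():
        evs = sorted(by_chrom.get(chrom, []), key=lambda e: e.position)
        for a, b in zip(evs, evs[1:]):
            if b.position <= a.position + a.tsd_length:
                raise ParameterError(f"overlapping events at {chrom}:"
                                     f"{a.position} and {chrom}:{b.position}")
        parts: list[str] = []
        blist: list[_Block] = []
        cursor = 0       # 0-based reference cursor
        dpos = 0         # donor cursor
        for e in evs:
            p0 = e.position - 1
            left = ref[cursor: p0 + e.tsd_length]
            parts.append(left)
            blist.append(_Block(dpos, dpos + len(left), "ref", ref_start=cursor))
            dpos += len(left)
            elem = elements[e.element_id]
            seq = elem.seq if e.orientation == "+" else revcomp(elem.seq)
            exp_ltr = (elem.ltr.seq if e.orientation == "+"
                       else revcomp(elem.ltr.seq))
            t = TruthRecord(chrom, e.position, e.element_kind, e.element_id,
                            e.orientation, e.tsd_length,
                            ref[p0: p0 + e.tsd_length], elem.subtype,
                            elem.perv_type or "", dpos, dpos + len(seq), exp_ltr)
            truth.append(t)
            parts.append(seq)
            blist.append(_Block(dpos, dpos + len(seq), "elem", truth=t))
            dpos += len(seq)
            cursor = p0
        tail = ref[cursor:]
        parts.append(tail)
        blist.append(_Block(dpos, dpos + len(tail), "ref", ref_start=cursor))
        donor[chrom] = "".join(parts)
        blocks[chrom] = blist
    return DonorGenome(seqs=donor, blocks=blocks, truth=truth,
                       reference_lengths={c: len(s) for c, s in reference.items()})


# ==========================================================================
# Read simulation
# ==========================================================================


@dataclass(slots=True)
class ReadSimParams:
    read_length: int = 150
    fragment_mean: int = 350
    fragment_sd: int = 35
    coverage: float = 50.0
    per_base_error: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.fragment_mean <= self.read_length:
            raise ParameterError("fragment_mean must exceed read_length")
        if self.coverage <= 0:
            raise ParameterError("coverage must be positive")

    @property
    def span_lo(self) -> int:
        return max(self.read_length + 1,
                   self.fragment_mean - 3 * self.fragment_sd)

    @property
    def span_hi(self) -> int:
        return self.fragment_mean + 3 * self.fragment_sd


@dataclass(slots=True)
class SimPair:
    r1: AlignedRead
    r2: AlignedRead
    truth_class: str          # proper | discordant | singleton | soft_clipped | unmapped_pair


@dataclass
class ReadSet:
    """Simulated read pairs with truth alignments and class labels."""

    pairs: list[SimPair]
    reference_lengths: dict[str, int]
    params: ReadSimParams

    def reads(self) -> Iterable[AlignedRead]:
        for p in self.pairs:
            yield p.r1
            yield p.r2

    def write_sam(self, path: str | Path) -> None:
        write_sam(self.reads(), self.reference_lengths, path)

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        def gen():
            for p in self.pairs:
                yield p.r1.name, _sequenced(p.r1), _sequenced(p.r2)
        write_fastq_pair(gen(), path1, path2)


def _sequenced(read: AlignedRead) -> str:
    """Sequence in sequencing orientation (as it would appear in FASTQ)."""
    if read.is_mapped and read.is_reverse:
        return revcomp(read.seq)
    return read.seq


@dataclass(slots=True)
class _Placement:
    mapped: bool
    pos: int = 0              # 1-based
    cigar: str = "*"
    clip_left: int = 0
    clip_right: int = 0


def _place(blocks: list[_Block], starts: list[int], s: int, e: int) -> _Placement:
    """Truth alignment of donor interval [s, e) against the reference."""
    i = bisect_right(starts, s) - 1
    b = blocks[i]
    if e <= b.donor_end:
        if b.kind == "ref":
            return _Placement(True, b.ref_start + (s - b.donor_start) + 1,
                              f"{e - s}M")
        return _Placement(False)
    nxt = blocks[i + 1]
    if e > nxt.donor_end:       # would need to span a whole block
        return _Placement(False)
    if b.kind == "ref":         # ref -> element: clipped on the right
        m = b.donor_end - s
        if m < MIN_ANCHOR_BP:
            return _Placement(False)
        return _Placement(True, b.ref_start + (s - b.donor_start) + 1,
                          f"{m}M{e - b.donor_end}S", clip_right=e - b.donor_end)
    # element -> ref: clipped on the left
    m = e - nxt.donor_start
    if m < MIN_ANCHOR_BP:
        return _Placement(False)
    return _Placement(True, nxt.ref_start + 1,
                      f"{nxt.donor_start - s}S{m}M",
                      clip_left=nxt.donor_start - s)


def _classify_truth(p1: _Placement, p2: _Placement, tlen: int,
                    params: ReadSimParams) -> str:
    if not p1.mapped and not p2.mapped:
        return "unmapped_pair"
    if p1.mapped != p2.mapped:
        return "singleton"
    if max(p1.clip_left, p1.clip_right, p2.clip_left, p2.clip_right) >= MIN_CLIP_BP:
        return "soft_clipped"
    if params.span_lo <= abs(tlen) <= params.span_hi:
        return "proper"
    return "discordant"


def simulate_reads(donor: DonorGenome, params: ReadSimParams) -> ReadSet:
    """Uniform fragment sampling from the donor with truth alignments.

    Fragment lengths are drawn from a normal distribution truncated at
    ±3 sd (matching the discovery module's proper-pair span window), so on
    error-free data the truth class labels are exactly reproducible from the
    alignments.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    pairs: list[SimPair] = []
    for chrom in sorted(donor.seqs):
        seq = donor.seqs[chrom]
        blocks = donor.blocks[chrom]
        starts = [b.donor_start for b in blocks]
        n_frags = int(round(params.coverage * len(seq) / (2 * rl)))
        flens = np.clip(np.rint(rng.normal(params.fragment_mean,
                                           params.fragment_sd, n_frags)),
                        params.span_lo, params.span_hi).astype(np.int64)
        flens = np.minimum(flens, len(seq))
        starts_arr = (rng.random(n_frags) * (len(seq) - flens + 1)).astype(np.int64)
        firsts = rng.random(n_frags) < 0.5
        if params.per_base_error > 0:
            err_draws = rng.random((n_frags, 2 * rl))
            err_bases = rng.integers(1, 4, (n_frags, 2 * rl))
        for i in range(n_frags):
            s = int(starts_arr[i]); flen = int(flens[i])
            e = s + flen
            left = seq[s: s + rl]
            right = seq[e - rl: e]
            if params.per_base_error > 0:
                left = _apply_errors(left, err_draws[i, :rl],
                                     err_bases[i, :rl], params.per_base_error)
                right = _apply_errors(right, err_draws[i, rl:],
                                      err_bases[i, rl:], params.per_base_error)
            pl = _place(blocks, starts, s, s + rl)
            pr = _place(blocks, starts, e - rl, e)
            name = f"frag_{chrom}_{i:07d}"
            pairs.append(_make_pair(name, chrom, left, right, pl, pr,
                                    bool(firsts[i]), params))
    return ReadSet(pairs=pairs, reference_lengths=donor.reference_lengths,
                   params=params)


_ERR_SHIFT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _apply_errors(seq: str, draws: np.ndarray, picks: np.ndarray,
                  rate: float) -> str:
    hits = np.flatnonzero(draws < rate)
    if not len(hits):
        return seq
    chars = list(seq)
    for i in hits:
        chars[i] = _ERR_SHIFT[chars[i]][picks[i] - 1]
    return "".join(chars)


def _make_pair(name: str, chrom: str, left: str, right: str,
               pl: _Placement, pr: _Placement, left_is_read1: bool,
               params: ReadSimParams) -> SimPair:
    # template length on the reference (0 when either mate is unmapped)
    tlen = 0
    if pl.mapped and pr.mapped:
        r_ref_span = sum(int(n) for n, o in re.findall(r"(\d+)([A-Z])", pr.cigar)
                         if o == "M")
        tlen = (pr.pos + r_ref_span - 1) - pl.pos + 1
    cls = _classify_truth(pl, pr, tlen, params)
    proper = cls == "proper"

    def flags(mine: _Placement, other: _Placement, is_left: bool, is_read1: bool) -> int:
        f = FLAG_PAIRED
        f |= FLAG_READ1 if is_read1 else FLAG_READ2
        if proper:
            f |= FLAG_PROPER
        if not mine.mapped:
            f |= FLAG_UNMAPPED
        if not other.mapped:
            f |= FLAG_MATE_UNMAPPED
        if mine.mapped and not is_left:
            f |= FLAG_REVERSE
        if other.mapped and is_left is True:
            f |= FLAG_MATE_REVERSE
        return f

    def build(mine: _Placement, other: _Placement, seq_fwd: str,
              is_left: bool, is_read1: bool) -> AlignedRead:
        if mine.mapped:
            stored = seq_fwd                      # reference-forward orientation
        else:
            stored = seq_fwd if is_left else revcomp(seq_fwd)  # raw sequencing orientation
        pos = mine.pos if mine.mapped else (other.pos if other.mapped else 0)
        rchrom = chrom if (mine.mapped or other.mapped) else None
        mpos = other.pos if other.mapped else (mine.pos if mine.mapped else 0)
        return AlignedRead(
            name=name, flag=flags(mine, other, is_left, is_read1),
            chrom=rchrom, pos=pos, mapq=60 if mine.mapped else 0,
            cigar=mine.cigar if mine.mapped else "*", seq=stored,
            mate_chrom=rchrom if (other.mapped or mine.mapped) else None,
            mate_pos=mpos,
            tlen=(tlen if is_left else -tlen) if (pl.mapped and pr.mapped) else 0)

    rleft = build(pl, pr, left, True, left_is_read1)
    rright = build(pr, pl, right, False, not left_is_read1)
    r1, r2 = (rleft, rright) if left_is_read1 else (rright, rleft)
    return SimPair(r1=r1, r2=r2, truth_class=cls)
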