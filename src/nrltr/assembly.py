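"""Local junction assembly and LTR reconstruction.

Reads mapping within a small window of a detected TSD are assembled, per
side, with a greedy overlap-layout-consensus assembler (best overlap first,
deterministic content-based tie-breaks, per-column majority consensus).  A
contig whose one end matches the reference flank and whose other end matches
the LTR library is a junction contig; the 5' and 3' junction contigs are
overlap-merged and the region between the two TSD copies is reported as the
reconstructed LTR.  Provirus internals are deliberately not assembled from
short reads; because the two LTR copies of a provirus are (near-)identical,
its two junctions reconstruct a single LTR and any divergence between the
copies shows up in ``overlap_mismatches``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .align import LocalAlignment, local_align
from .calling import TsdResult
from .errors import ParameterError
from .formats import AlignedRead, CallRecord
from .util import BASES, revcomp, seq_to_array

_KMER = 12          # shared-kmer gate before attempting an approximate overlap
_SLACK = 5          # end-anchoring slack (bp) for junction partitioning


# ==========================================================================
# Contigs
# ==========================================================================


class Contig:
    """Consensus sequence with per-column base counts (= coverage)."""

    __slots__ = ("counts", "n_reads", "sequence", "_kmers", "_kmers_rc",
                 "_posmap", "_posmap_rc")

    def __init__(self, counts: np.ndarray, n_reads: int):
        self.counts = counts
        self.n_reads = n_reads
        self.sequence = "".join(BASES[i] for i in counts.argmax(axis=1))
        self._kmers: frozenset | None = None
        self._kmers_rc: frozenset | None = None
        self._posmap: dict | None = None
        self._posmap_rc: dict | None = None

    @classmethod
    def from_seq(cls, seq: str, multiplicity: int = 1) -> "Contig":
        enc = seq_to_array(seq)
        counts = np.zeros((len(seq), 4), dtype=np.int32)
        ok = enc < 4
        counts[np.flatnonzero(ok), enc[ok]] = multiplicity
        return cls(counts, multiplicity)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def kmers(self, rc: bool = False) -> frozenset:
        if rc:
            if self._kmers_rc is None:
                s = revcomp(self.sequence)
                self._kmers_rc = frozenset(
                    s[i:i + _KMER] for i in range(len(s) - _KMER + 1))
            return self._kmers_rc
        if self._kmers is None:
            s = self.sequence
            self._kmers = frozenset(
                s[i:i + _KMER] for i in range(len(s) - _KMER + 1))
        return self._kmers

    def posmap(self, rc: bool = False) -> dict:
        """kmer -> tuple of start positions (capped at 4 per kmer)."""
        cached = self._posmap_rc if rc else self._posmap
        if cached is None:
            s = revcomp(self.sequence) if rc else self.sequence
            cached = {}
            for i in range(len(s) - _KMER + 1):
                k = s[i:i + _KMER]
                lst = cached.get(k)
                if lst is None:
                    cached[k] = [i]
                elif len(lst) < 4:
                    lst.append(i)
            if rc:
                self._posmap_rc = cached
            else:
                self._posmap = cached
        return cached

    def reverse_complement(self) -> "Contig":
        # complement = swap A<->T and C<->G count columns, then reverse rows
        c = Contig.__new__(Contig)
        c.counts = self.counts[::-1, [3, 2, 1, 0]].copy()
        c.n_reads = self.n_reads
        c.sequence = revcomp(self.sequence)
        c._kmers = self._kmers_rc
        c._kmers_rc = self._kmers
        c._posmap = self._posmap_rc
        c._posmap_rc = self._posmap
        return c


def _merge_counts(a: Contig, b: Contig, offset: int) -> tuple[Contig, int]:
    """Overlay ``b`` onto ``a`` at ``offset`` (gapless); returns the merged
    contig and the number of disagreeing overlap columns."""
    L = max(len(a), offset + len(b))
    counts = np.zeros((L, 4), dtype=np.int32)
    counts[:len(a)] += a.counts
    counts[offset:offset + len(b)] += b.counts
    lo, hi = offset, min(len(a), offset + len(b))
    mism = int(np.sum(a.counts[lo:hi].argmax(axis=1)
                      != b.counts[lo - offset:hi - offset].argmax(axis=1)))
    return Contig(counts, a.n_reads + b.n_reads), mism


@dataclass(slots=True)
class _Overlap:
    score: float
    a_first: bool            # a's suffix overlaps b's prefix (else b first)
    b_rc: bool
    offset: int              # position of the later sequence in the earlier
    length: int
    mismatches: int


def _exact_offset(sa: str, sb: str, min_overlap: int) -> tuple[int, int] | None:
    """Largest k with sa[-k:] == sb[:k] (k >= min_overlap), incl. containment;
    returns (offset, overlap_length)."""
    if sb in sa:
        return sa.find(sb), len(sb)
    seed = sb[:_KMER]
    start = max(0, len(sa) - len(sb))
    i = sa.find(seed, start)
    while i != -1:
        k = len(sa) - i
        if k >= min_overlap and k <= len(sb) and sa.endswith(sb[:k]):
            return i, k
        i = sa.find(seed, i + 1)
    return None



def _mismatches(x: str, y: str) -> int:
    ax = np.frombuffer(x.encode(), dtype=np.uint8)
    ay = np.frombuffer(y.encode(), dtype=np.uint8)
    return int((ax != ay).sum())


def _diagonal_overlap(a: Contig, b: Contig, b_rc: bool, min_overlap: int,
                      min_identity: float) -> tuple[_Overlap | None, int]:
    """Gapless overlap via shared-kmer diagonals.

    Substitution errors leave overlaps gapless, so candidate placements of
    ``b`` on ``a`` are the diagonals supported by shared 12-mers; each is
    verified by direct mismatch counting.  Returns the best placement and
    the number of diagonals tested.
    """
    shared = a.kmers() & b.kmers(b_rc)
    if not shared:
        return None, 0
    sa = a.sequence
    sb = revcomp(b.sequence) if b_rc else b.sequence
    pa, pb = a.posmap(), b.posmap(b_rc)
    diagonals: set[int] = set()
    for k in sorted(shared)[:8]:
        for i in pa[k]:
            for j in pb[k]:
                diagonals.add(i - j)
    best: _Overlap | None = None
    tested = 0
    for o in sorted(diagonals):
        lo = max(0, o)
        hi = min(len(sa), o + len(sb))
        span = hi - lo
        if span < min_overlap:
            continue
        tested += 1
        mism = _mismatches(sa[lo:hi], sb[lo - o:hi - o])
        if 1 - mism / span < min_identity:
            continue
        score = float(span - mism)
        if o >= 0:
            cand = _Overlap(score, True, b_rc, o, span, mism)
        else:
            cand = _Overlap(score, False, b_rc, -o, span, mism)
        if best is None or cand.score > best.score:
            best = cand
    return best, tested


def _best_overlap(a: Contig, b: Contig, min_overlap: int, min_identity: float,
                  allow_approx: bool = True) -> _Overlap | None:
    best: _Overlap | None = None
    for b_rc in (False, True):
        sb = revcomp(b.sequence) if b_rc else b.sequence
        for a_first in (True, False):
            sx, sy = (a.sequence, sb) if a_first else (sb, a.sequence)
            hit = _exact_offset(sx, sy, min_overlap)
            if hit is not None:
                off, k = hit
                cand = _Overlap(float(k), a_first, b_rc, off, k, 0)
                if best is None or cand.score > best.score:
                    best = cand
    if best is None and allow_approx:
        for b_rc in (False, True):
            cand, _ = _diagonal_overlap(a, b, b_rc, min_overlap, min_identity)
            if cand is not None and (best is None or cand.score > best.score):
                best = cand
    return best


def assemble(reads: Sequence[str], min_overlap: int = 40,
             min_overlap_identity: float = 0.90) -> list[Contig]:
    """Greedy overlap-layout-consensus assembly of a read set.

    Duplicate reads collapse into multiplicity, contained reads into their
    container; then the highest-scoring pairwise overlap (both orientations,
    ties broken on sequence content so the result is input-order invariant)
    is merged repeatedly until no overlap of ``min_overlap`` bases at
    ``min_overlap_identity`` remains.  Consensus is per-column majority with
    ties resolved in A<C<G<T order.
    """
    seqs = [s for s in reads if s]
    if not seqs:
        raise ParameterError("assemble requires at least one read")
    mult: dict[str, int] = {}
    for s in seqs:
        canon = min(s, revcomp(s))
        mult[canon] = mult.get(canon, 0) + 1
    # containment collapse (deterministic: sorted by length desc, then seq)
    ordered = sorted(mult, key=lambda s: (-len(s), s))
    containers: list[str] = []
    extra: dict[str, list[tuple[int, str]]] = {}
    for s in ordered:
        placed = False
        for big in containers:
            for variant in (s, revcomp(s)):
                off = big.find(variant)
                if off != -1:
                    extra.setdefault(big, []).append((off, variant))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            containers.append(s)

    contigs: dict[int, Contig] = {}
    for i, s in enumerate(containers):
        c = Contig.from_seq(s, mult[s])
        for off, variant in extra.get(s, []):
            c, _ = _merge_counts(c, Contig.from_seq(variant, mult[variant]), off)
        contigs[i] = c
    next_id = len(containers)

    heap: list = []

    def push(i: int, j: int):
        a, b = contigs[i], contigs[j]
        ov = _best_overlap(a, b, min_overlap, min_overlap_identity)
        if ov is not None:
            key = (-ov.score, -ov.length,
                   min(a.sequence, b.sequence), max(a.sequence, b.sequence))
            heapq.heappush(heap, (key, i, j, ov))

    ids = sorted(contigs)
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            push(ids[x], ids[y])

    while heap:
        _, i, j, ov = heapq.heappop(heap)
        if i not in contigs or j not in contigs:
            continue
        a, b = contigs.pop(i), contigs.pop(j)
        bb = b.reverse_complement() if ov.b_rc else b
        first, second = (a, bb) if ov.a_first else (bb, a)
        merged, _ = _merge_counts(first, second, ov.offset)
        nid = next_id
        next_id += 1
        contigs[nid] = merged
        for other in sorted(contigs):
            if other != nid:
                push(other, nid)
    return sorted(contigs.values(), key=lambda c: (-len(c), c.sequence))


# ==========================================================================
# Junction read extraction
# ==========================================================================


def extract_junction_reads(pairs: Iterable[tuple[AlignedRead, AlignedRead]],
                           chrom: str, center: int, window: int = 150,
                           min_clip: int = 10) -> tuple[list[str], list[str]]:
    """Split reads near a breakpoint/TSD into 5' and 3' assembly sets.

    A mapped read whose alignment overlaps ``center ± window`` joins the 5'
    set when right-clipped (or centred upstream) and the 3' set when
    left-clipped (or centred downstream).  The unmapped mate of an in-window
    anchor joins its anchor's side (forward anchor -> 5', reverse -> 3').
    Sequences are returned reference-forward for mapped reads and raw for
    unmapped mates (the assembler tries both orientations).
    """
    lo, hi = center - window, center + window
    side5: list[str] = []
    side3: list[str] = []
    for r1, r2 in pairs:
        for read, mate in ((r1, r2), (r2, r1)):
            if not read.is_mapped or read.chrom != chrom:
                continue
            if read.end < lo or read.pos > hi:
                continue
            if read.clip_right >= min_clip:
                side5.append(read.seq)
            elif read.clip_left >= min_clip:
                side3.append(read.seq)
            elif (read.pos + read.end) // 2 <= center:
                side5.append(read.seq)
            else:
                side3.append(read.seq)
            if not mate.is_mapped:
                (side5 if not read.is_reverse else side3).append(mate.seq)
    return side5, side3


# ==========================================================================
# Junction analysis and LTR reconstruction
# ==========================================================================


@dataclass(slots=True)
class JunctionContig:
    """A contig with one end on the reference and the other in the library."""

    contig: Contig
    ref_start: int            # 1-based inclusive reference span of the
    ref_end: int              # reference-matching contig end
    nonref_start: int         # 0-based half-open contig coordinates of the
    nonref_end: int           # non-reference segment
    nonref_element: str
    nonref_identity: float
    junction_side: str        # "5p" | "3p"

    @property
    def nonref_seq(self) -> str:
        return self.contig.sequence[self.nonref_start:self.nonref_end]

    def nonref_contig(self) -> Contig:
        return Contig(self.contig.counts[self.nonref_start:self.nonref_end].copy(),
                      self.contig.n_reads)


def analyze_junction(contig: Contig, reference: dict[str, str],
                     call: CallRecord, library: dict[str, str],
                     min_identity: float = 0.80, min_nonref: int = 30,
                     flank: int = 1000,
                     tsd: TsdResult | None = None) -> JunctionContig | None:
    """Partition a contig into reference flank + library-matching remainder.

    The contig is aligned to the ±``flank`` reference window around the
    call (both orientations; minus-strand contigs are flipped); the
    unaligned remainder (>= ``min_nonref`` bp at one end) must hit the LTR
    library at >= ``min_identity`` for a junction to be reported.  When the
    TSD is known the flank window is clipped at the TSD boundary before the
    final alignment, so chance matches between element bases and the
    opposite flank cannot drag the junction across the insertion point.
    """
    chrom_seq = reference[call.chrom]
    w0 = max(0, call.breakpoint_pos - 1 - flank)
    window = chrom_seq[w0: call.breakpoint_pos - 1 + flank]
    if not window:
        return None
    aln = local_align(contig.sequence, window)
    aln_rc = local_align(revcomp(contig.sequence), window)
    if aln_rc.score > aln.score:
        contig = contig.reverse_complement()
        aln = aln_rc
    if aln.empty:
        return None
    n = len(contig)

    def partition(a: LocalAlignment) -> tuple[tuple[int, int], str] | None:
        if a.query_start <= _SLACK and n - a.query_end >= min_nonref:
            return (a.query_end, n), "5p"       # flank ... junction ... element
        if n - a.query_end <= _SLACK and a.query_start >= min_nonref:
            return (0, a.query_start), "3p"     # element ... junction ... flank
        return None

    part = partition(aln)
    if part is None:
        return None
    _, side = part
    if tsd is not None:
        if side == "5p":
            w0c, window = w0, chrom_seq[w0: tsd.tsd_end]
        else:
            w0c, window = tsd.tsd_start - 1, chrom_seq[tsd.tsd_start - 1:
                                                       call.breakpoint_pos - 1 + flank]
        refined = local_align(contig.sequence, window)
        part2 = partition(refined)
        if part2 is not None and part2[1] == side:
            aln, w0 = refined, w0c
            part = part2
    nonref, side = part
    remainder = contig.sequence[nonref[0]:nonref[1]]
    from .align import best_library_hit
    hit = best_library_hit(remainder, library, min_identity=min_identity,
                           min_length=min(min_nonref, len(remainder)))
    if hit is None:
        return None
    return JunctionContig(
        contig=contig,
        ref_start=w0 + aln.target_start + 1,
        ref_end=w0 + aln.target_end,
        nonref_start=nonref[0], nonref_end=nonref[1],
        nonref_element=hit.element, nonref_identity=hit.alignment.identity,
        junction_side=side)


@dataclass(slots=True)
class ReconstructedLTR:
    """The TSD-to-TSD reconstruction of an inserted LTR at one locus."""

    chrom: str
    position: int             # call breakpoint (1-based)
    sequence: str
    tsd5: TsdResult | None
    tsd3: TsdResult | None
    completeness: str         # "both" | "5p_only" | "3p_only"
    overlap_mismatches: int
    element: str | None = None

    @property
    def length_with_tsd(self) -> int:
        return len(self.sequence)

    @property
    def ltr_seq(self) -> str:
        """Element sequence with the flanking TSD copies stripped."""
        s = self.sequence
        if self.tsd5 is not None:
            s = s[self.tsd5.length:]
        if self.tsd3 is not None and self.completeness == "both":
            s = s[:-self.tsd3.length]
        elif self.tsd3 is not None and self.completeness == "3p_only":
            s = s[:-self.tsd3.length]
        return s


def reconstruct_ltr(call: CallRecord, j5: JunctionContig | None,
                    j3: JunctionContig | None, tsd: TsdResult | None,
                    min_merge_overlap: int = 20,
                    min_merge_identity: float = 0.90) -> ReconstructedLTR | None:
    """Combine junction contigs into the TSD-to-TSD LTR sequence.

    With both junctions, their non-reference segments are overlap-merged
    (coverage-weighted majority consensus; disagreeing columns are counted
    in ``overlap_mismatches``, never silently resolved away).  Segments
    that cannot be joined fall back to the longer single side rather than
    guessing.  A TSD copy is attributed to a side only when that side's
    contig actually spans the TSD interval.
    """
    if j5 is None and j3 is None:
        return None
    tsd5 = tsd if (tsd and j5 and j5.ref_end >= tsd.tsd_end - 1) else None
    tsd3 = tsd if (tsd and j3 and j3.ref_start <= tsd.tsd_start + 1) else None
    element = j5.nonref_element if j5 else j3.nonref_element

    def seg5(j: JunctionContig) -> Contig:
        # anchor the element start on the TSD: the flank alignment may have
        # drifted past the junction on chance base matches
        start = j.nonref_start
        if tsd is not None:
            start = max(0, min(len(j.contig), start - (j.ref_end - tsd.tsd_end)))
        return Contig(j.contig.counts[start:].copy(), j.contig.n_reads)

    def seg3(j: JunctionContig) -> Contig:
        end = j.nonref_end
        if tsd is not None:
            end = max(0, min(len(j.contig), end + (tsd.tsd_start - j.ref_start)))
        return Contig(j.contig.counts[:end].copy(), j.contig.n_reads)

    merged: Contig | None = None
    mismatches = 0
    if j5 and j3:
        e5, e3 = seg5(j5), seg3(j3)
        ov = _best_overlap(e5, e3, min_merge_overlap, min_merge_identity,
                           allow_approx=True)
        if ov is not None and not ov.b_rc and ov.a_first:
            merged, mismatches = _merge_counts(e5, e3, ov.offset)
        else:
            # cannot be joined: report the longer side only
            if len(e5) >= len(e3):
                j3, tsd3 = None, None
            else:
                j5, tsd5 = None, None
    if merged is not None and tsd5 and tsd3:
        completeness = "both"
        seq = tsd.tsd_seq + merged.sequence + tsd.tsd_seq
    elif merged is not None:
        completeness = "5p_only" if tsd5 or not tsd3 else "3p_only"
        core = merged.sequence
        if tsd5:
            seq = tsd.tsd_seq + core
        elif tsd3:
            seq = core + tsd.tsd_seq
        else:
            seq = core
    elif j5 is not None:
        completeness = "5p_only"
        seq = (tsd.tsd_seq if tsd5 else "") + seg5(j5).sequence
    else:
        completeness = "3p_only"
        seq = seg3(j3).sequence + (tsd.tsd_seq if tsd3 else "")
    return ReconstructedLTR(chrom=call.chrom, position=call.breakpoint_pos,
                            sequence=seq, tsd5=tsd5, tsd3=tsd3,
                            completeness=completeness,
                            overlap_mismatches=mismatches, element=element)
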