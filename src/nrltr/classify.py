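"""LTR classification: alignment, distances, trees and U3 repeat structure.

The endogenous-retrovirus LTRs recovered by the pipeline fall into two
families distinguished by their U3 promoter/enhancer region: B-type LTRs
carry tandem arrays of 18-bp and 21-bp repeat units (subtypes B1/B2/B3 by
total copy number), while A-type LTRs lack full 18/21-bp arrays and are split
into A2 (shorter 8-15 bp sub-repeat arrays present) and A1 (none).  Family
structure is recovered independently by a phylogenetic route: progressive
multiple alignment, Kimura three-parameter (K3P) distances and a
neighbor-joining tree whose deepest split separates the two families.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage

from .align import local_align_both_strands
from .errors import ParameterError, UndefinedDistanceError
from .util import BASES, revcomp, seq_to_array

# ==========================================================================
# Progressive multiple alignment
# ==========================================================================


@dataclass
class MultipleAlignment:
    """Aligned rows (gap character '-'), one per input sequence, same order."""

    names: list[str]
    rows: list[str]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]


_GAP_OPEN = 4.0
_GAP_EXT = 1.0
_NEG = -1.0e30


class _Profile:
    """A set of aligned rows plus per-column base counts."""

    __slots__ = ("indices", "rows", "counts")

    def __init__(self, indices: list[int], rows: list[str], counts: np.ndarray):
        self.indices = indices
        self.rows = rows
        self.counts = counts        # (n_columns, 4) float

    @classmethod
    def from_seq(cls, index: int, seq: str) -> "_Profile":
        enc = seq_to_array(seq)
        counts = np.zeros((len(seq), 4))
        ok = enc < 4
        counts[np.flatnonzero(ok), enc[ok]] = 1.0
        return cls([index], [seq], counts)


def _profile_dp(pa: _Profile, pb: _Profile) -> tuple[list[int | None], list[int | None]]:
    """Global affine profile-profile alignment (match +1 / mismatch -1 /
    open -4 / extend -1); returns per-output-column source indices."""
    ca, cb = pa.counts, pb.counts
    na = ca.sum(axis=1, keepdims=True)
    nb = cb.sum(axis=1, keepdims=True)
    fa = np.divide(ca, na, out=np.zeros_like(ca), where=na > 0)
    fb = np.divide(cb, nb, out=np.zeros_like(cb), where=nb > 0)
    S = 2.0 * (fa @ fb.T) - 1.0
    la, lb = S.shape

    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)   # gap columns in B (A advances)
    Y = np.full((la + 1, lb + 1), _NEG)   # gap columns in A (B advances)
    M[0, 0] = 0.0
    j = np.arange(1, lb + 1, dtype=float)
    Y[0, 1:] = -(_GAP_OPEN + (j - 1) * _GAP_EXT)
    for i in range(1, la + 1):
        X[i] = np.maximum(M[i - 1] - _GAP_OPEN, X[i - 1] - _GAP_EXT)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        # Y[i, j] = max_{k<j} M[i, k] - open - (j-1-k)*ext, vectorised scan
        run = np.maximum.accumulate(M[i, :-1] + _GAP_EXT * np.arange(lb))
        Y[i, 1:] = run - _GAP_OPEN - _GAP_EXT * (j - 1)

    i, jj = la, lb
    state = int(np.argmax([M[i, jj], X[i, jj], Y[i, jj]]))
    out_a: list[int | None] = []
    out_b: list[int | None] = []
    eps = 1e-9
    while i > 0 or jj > 0:
        if state == 0:
            out_a.append(i - 1)
            out_b.append(jj - 1)
            prev = [M[i - 1, jj - 1], X[i - 1, jj - 1], Y[i - 1, jj - 1]]
            i, jj = i - 1, jj - 1
            state = int(np.argmax(prev))
        elif state == 1:
            out_a.append(i - 1)
            out_b.append(None)
            state = 0 if X[i, jj] <= M[i - 1, jj] - _GAP_OPEN + eps else 1
            i -= 1
        else:
            out_a.append(None)
            out_b.append(jj - 1)
            state = 0 if Y[i, jj] <= M[i, jj - 1] - _GAP_OPEN + eps else 2
            jj -= 1
        if i == 0 and jj > 0 and state == 0:
            state = 2
        if jj == 0 and i > 0 and state == 0:
            state = 1
    out_a.reverse()
    out_b.reverse()
    return out_a, out_b


def _merge(pa: _Profile, pb: _Profile) -> _Profile:
    cols_a, cols_b = _profile_dp(pa, pb)
    L = len(cols_a)
    counts = np.zeros((L, 4))
    ia = [k for k, c in enumerate(cols_a) if c is not None]
    ib = [k for k, c in enumerate(cols_b) if c is not None]
    counts[ia] += pa.counts
    counts[ib] += pb.counts

    def expand(rows: list[str], cols: list[int | None]) -> list[str]:
        return ["".join(r[c] if c is not None else "-" for c in cols)
                for r in rows]

    return _Profile(pa.indices + pb.indices,
                    expand(pa.rows, cols_a) + expand(pb.rows, cols_b), counts)


def _kmer_distance(a: str, b: str, k: int = 6) -> float:
    sa = {a[i:i + k] for i in range(len(a) - k + 1)}
    sb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def align_progressive(seqs: dict[str, str] | Sequence[tuple[str, str]]) -> MultipleAlignment:
    """Progressive multiple alignment along a k-mer/UPGMA guide tree.

    Deterministic: the guide tree comes from average-linkage clustering of
    6-mer distances and profiles are merged by global affine alignment.
    A single sequence is returned unchanged as a one-row alignment.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    names = [n for n, _ in items]
    if not items:
        raise ParameterError("no sequences to align")
    if len(items) == 1:
        return MultipleAlignment(names, [items[0][1]])
    profiles: dict[int, _Profile] = {
        i: _Profile.from_seq(i, s) for i, (_, s) in enumerate(items)}
    if len(items) == 2:
        final = _merge(profiles[0], profiles[1])
    else:
        n = len(items)
        cond = [ _kmer_distance(items[i][1], items[j][1])
                 for i in range(n) for j in range(i + 1, n)]
        Z = linkage(np.asarray(cond), method="average")
        for t, (a, b, _, _) in enumerate(Z):
            profiles[n + t] = _merge(profiles.pop(int(a)), profiles.pop(int(b)))
        final = profiles[n + len(Z) - 1]
    order = np.argsort(final.indices)
    rows = [final.rows[i] for i in order]
    return MultipleAlignment(names, rows)


# ==========================================================================
# Kimura three-parameter distance
# ==========================================================================

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_TV_Q = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}   # A<->T / G<->C
_TV_R = {("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")}   # A<->C / G<->T

SATURATION_CEILING = 5.0


def k3p_distance(row_a: str, row_b: str,
                 saturation_ceiling: float = SATURATION_CEILING) -> float:
    """Kimura three-parameter distance between two aligned rows.

    With P the transition proportion and Q, R the two transversion-class
    proportions over columns where both rows carry an unambiguous base,

        d = -(1/4) * ln[(1 - 2P - 2Q)(1 - 2P - 2R)(1 - 2Q - 2R)]

    Saturated pairs (any log factor <= 0) are reported at the configured
    ceiling.  Columns with a gap or N in either row are excluded; zero
    comparable columns raises :class:`UndefinedDistanceError`.
    """
    if len(row_a) != len(row_b):
        raise ParameterError("rows must come from one alignment")
    ea, eb = seq_to_array(row_a), seq_to_array(row_b)
    ok = (ea < 4) & (eb < 4)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable columns")
    a, b = ea[ok], eb[ok]
    diff = a != b
    # base encoding A=0 C=1 G=2 T=3: purines even, pyrimidines odd;
    # the A<->T and G<->C pairs are exactly those summing to 3
    transition = diff & ((a % 2) == (b % 2))
    q_class = diff & ((a + b) == 3)
    r_class = diff & ~transition & ~q_class
    P = transition.sum() / n
    Q = q_class.sum() / n
    R = r_class.sum() / n
    f1 = 1 - 2 * P - 2 * Q
    f2 = 1 - 2 * P - 2 * R
    f3 = 1 - 2 * Q - 2 * R
    if min(f1, f2, f3) <= 0:
        return saturation_ceiling
    return -0.25 * math.log(f1 * f2 * f3)


@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray
    saturated: np.ndarray

    def __post_init__(self):
        m = self.matrix
        assert m.shape == (len(self.names), len(self.names))
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)


def k3p_matrix(alignment: MultipleAlignment,
               saturation_ceiling: float = SATURATION_CEILING) -> DistanceMatrix:
    n = len(alignment.names)
    m = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d = k3p_distance(alignment.rows[i], alignment.rows[j],
                             saturation_ceiling)
            m[i, j] = m[j, i] = d
            sat[i, j] = sat[j, i] = d >= saturation_ceiling
    return DistanceMatrix(list(alignment.names), m, sat)


# ==========================================================================
# Neighbor joining
# ==========================================================================


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining; exact on additive matrices.

    Taxa are processed in name order (deterministic tie-break); negative
    branch lengths are clamped to zero with the deficit moved to the sister
    branch.  Returns an unrooted :class:`dendropy.Tree`.
    """
    if len(dist.names) < 3:
        raise ParameterError("neighbor joining needs >= 3 taxa")
    off = ~np.eye(len(dist.names), dtype=bool)
    if dist.saturated[off].all():
        raise ParameterError("all pairwise distances saturated; no signal")

    order = np.argsort(np.asarray(dist.names))
    names = [dist.names[i] for i in order]
    D = dist.matrix[np.ix_(order, order)].astype(float).copy()

    tns = dendropy.TaxonNamespace(names)
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=tns.get_taxon(n)) for n in names]
    active = list(range(len(names)))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        k = int(np.argmin(Q))           # first minimum in row-major order
        ai, aj = divmod(k, n)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (n - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        newd = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, newd])
        D = np.hstack([D, np.append(newd, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    root = dendropy.Node()
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ==========================================================================
# Tandem repeat detection and subtype calls
# ==========================================================================


@dataclass
class RepeatAnnotation:
    """A tandem array of ``copy_number`` full copies of a ``unit_length``-bp
    unit starting at ``start`` (0-based)."""

    unit_length: int
    start: int
    copy_number: int
    consensus: str
    mean_identity: float

    @property
    def starts(self) -> list[int]:
        return [self.start + k * self.unit_length
                for k in range(self.copy_number)]

    @property
    def end(self) -> int:
        return self.start + self.unit_length * self.copy_number


def _consensus(counts: np.ndarray) -> str:
    return "".join(BASES[i] for i in counts.argmax(axis=1))


def detect_repeats(seq: str, unit_lengths: Iterable[int] = (18, 21),
                   min_copies: int = 2,
                   max_unit_mismatch: int = 3) -> list[RepeatAnnotation]:
    """Scan every phase for tandem arrays of fixed-period repeat units.

    A seed window extends while the next unit-sized block matches the running
    consensus with at most ``max_unit_mismatch`` mismatches; overlapping
    arrays of the same period are deduplicated keeping the longest (then
    leftmost).  Partial trailing copies are not counted.
    """
    out: list[RepeatAnnotation] = []
    L = len(seq)
    for u in sorted(unit_lengths):
        if L < 2 * u:
            continue
        found: list[RepeatAnnotation] = []
        for start in range(0, L - 2 * u + 1):
            counts = np.zeros((u, 4))
            enc = seq_to_array(seq[start:start + u])
            counts[np.arange(u), np.clip(enc, 0, 3)] += 1
            copies = 1
            identities = []
            j = start + u
            while j + u <= L:
                block = seq[j:j + u]
                cons = _consensus(counts)
                mism = sum(x != y for x, y in zip(block, cons))
                if mism > max_unit_mismatch:
                    break
                enc = seq_to_array(block)
                counts[np.arange(u), np.clip(enc, 0, 3)] += 1
                identities.append((u - mism) / u)
                copies += 1
                j += u
            if copies >= min_copies:
                found.append(RepeatAnnotation(
                    u, start, copies, _consensus(counts),
                    float(np.mean(identities)) if identities else 1.0))
        found.sort(key=lambda a: (-a.copy_number, a.start))
        kept: list[RepeatAnnotation] = []
        for ann in found:
            if not any(k.start < ann.end and ann.start < k.end for k in kept):
                kept.append(ann)
        out.extend(sorted(kept, key=lambda a: a.start))
    return out


_TATA_RE = re.compile("TATA[AT]A")


def find_u3(seq: str, fallback_fraction: float = 0.65) -> tuple[int, int, bool]:
    """U3 span of an LTR: start of the sequence up to the TATA box.

    The first TATAWA motif in the 3' half marks the U3/R boundary; when no
    motif is found U3 defaults to the first ``fallback_fraction`` of the LTR.
    Returns ``(start, end, tata_found)`` (0-based half-open).
    """
    half = len(seq) // 2
    for m in _TATA_RE.finditer(seq):
        if m.start() >= half:
            return 0, m.start(), True
    return 0, int(len(seq) * fallback_fraction), False


@dataclass
class SubtypeCall:
    major: str                       # "A" | "B"
    minor: str                       # A1/A2/B1/B2/B3
    evidence: list[RepeatAnnotation]
    u3_span: tuple[int, int]
    orientation: str = "+"           # orientation in which U3 was read

    def __post_init__(self):
        if not self.minor.startswith(self.major):
            raise ParameterError("minor subtype inconsistent with major")


def _score_orientation(seq: str, sub_unit_range: tuple[int, int]):
    u3s, u3e, tata = find_u3(seq)
    u3 = seq[u3s:u3e]
    main = detect_repeats(u3, (18, 21), min_copies=2, max_unit_mismatch=3)
    main_copies = sum(a.copy_number for a in main)
    sub: list[RepeatAnnotation] = []
    for u in range(sub_unit_range[0], sub_unit_range[1] + 1):
        sub.extend(detect_repeats(u3, (u,), min_copies=2,
                                  max_unit_mismatch=u // 8))
    sub_copies = sum(a.copy_number for a in sub)
    return (int(tata), main_copies, sub_copies), (u3s, u3e), main, sub


def classify_subtype(ltr_seq: str, repeats: list[RepeatAnnotation] | None = None,
                     *, tier_boundaries: tuple[int, int] = (4, 6),
                     sub_unit_range: tuple[int, int] = (8, 15),
                     check_orientation: bool = True) -> SubtypeCall:
    """Assign the five-way U3 subtype of an LTR.

    Major type B requires both an 18-bp and a 21-bp tandem array (>= 2 full
    copies each) inside U3; B minors are tiers of the total 18+21 copy
    number (B1 <= ``tier_boundaries[0]`` < B2 <= ``tier_boundaries[1]`` < B3).
    A-type LTRs are A2 when any 8-15 bp sub-repeat array is present, else A1.
    Orientation handling makes the call invariant to reverse complementing
    the input: both orientations are scored (TATA box found, then repeat
    content) and the better one is read.
    """
    candidates = [("+", ltr_seq)]
    if check_orientation:
        candidates.append(("-", revcomp(ltr_seq)))
    scored = []
    for strand, seq in candidates:
        score, span, main, sub = _score_orientation(seq, sub_unit_range)
        scored.append((score, min(seq, revcomp(seq)) == seq, strand, span, main, sub))
    scored.sort(key=lambda t: (t[0], t[1]), reverse=True)
    _, _, strand, span, main, sub = scored[0]
    if repeats is not None and strand == "+":
        main = [a for a in repeats if a.unit_length in (18, 21)
                and a.copy_number >= 2 and a.end <= span[1]]
    has18 = any(a.unit_length == 18 and a.copy_number >= 2 for a in main)
    has21 = any(a.unit_length == 21 and a.copy_number >= 2 for a in main)
    if has18 and has21:
        total = sum(a.copy_number for a in main)
        if total <= tier_boundaries[0]:
            minor = "B1"
        elif total <= tier_boundaries[1]:
            minor = "B2"
        else:
            minor = "B3"
        return SubtypeCall("B", minor, main, span, strand)
    minor = "A2" if sub else "A1"
    return SubtypeCall("A", minor, sub, span, strand)


# ==========================================================================
# PERV A/B/C typing
# ==========================================================================


@dataclass
class TypeCall:
    perv_type: str          # A | B | C | unknown
    identity: float


def classify_perv_type(element_seq: str, typed_panel: dict[str, str],
                       min_identity: float = 0.80, min_length: int = 50,
                       tie_margin: float = 0.005) -> TypeCall:
    """Type an element by its best local hit against a typed marker panel.

    Each panel entry (a pol-region marker labelled A/B/C) is aligned to the
    element on both strands; the best-identity hit decides the type.  The
    call is ``unknown`` when the best hit is shorter than ``min_length``
    columns, below ``min_identity``, or when the top two types tie within
    ``tie_margin``.
    """
    if not typed_panel:
        raise ParameterError("typed panel must not be empty")
    hits = []
    for label, marker in sorted(typed_panel.items()):
        aln = local_align_both_strands(marker, element_seq)
        hits.append((aln.identity if aln.length >= min_length else 0.0,
                     aln.score, label))
    hits.sort(reverse=True)
    best_id, _, best_label = hits[0]
    if best_id < min_identity:
        return TypeCall("unknown", best_id)
    if len(hits) > 1 and hits[0][0] - hits[1][0] < tie_margin:
        return TypeCall("unknown", best_id)
    return TypeCall(best_label, best_id)
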