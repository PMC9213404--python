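"""Local pairwise alignment used for anchor evidence, junctions and assembly.

Smith–Waterman semantics with affine gaps (match +1, mismatch -1, gap open -2,
gap extend -1; a length-k gap costs 2 + (k - 1)).  The dynamic programming is
delegated to :class:`Bio.Align.PairwiseAligner`; this module owns the scoring
convention, the empty-alignment handling and the identity bookkeeping the rest
of the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from .errors import ParameterError
from .util import revcomp

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0
GAP_EXTEND = -1.0


@dataclass(slots=True)
class LocalAlignment:
    """Best local alignment of ``query`` against ``target``.

    Coordinates are 0-based half-open on the input strings; ``strand`` is the
    query strand relative to the target ("-" means the reverse complement of
    the query was aligned, with coordinates on the original query).
    """

    score: float
    matches: int
    length: int          # alignment columns (matches + mismatches + gaps)
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str = "+"

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0

    @property
    def empty(self) -> bool:
        return self.length == 0


EMPTY = LocalAlignment(0.0, 0, 0, 0, 0, 0, 0)


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, open_: float, extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = open_
    al.extend_gap_score = extend
    return al


def local_align(query: str, target: str, *, match: float = MATCH,
                mismatch: float = MISMATCH, gap_open: float = GAP_OPEN,
                gap_extend: float = GAP_EXTEND) -> LocalAlignment:
    """Best local alignment of ``query`` within ``target``.

    When no cell scores positively (e.g. disjoint alphabets) the empty
    alignment is returned with score 0.
    """
    if not query or not target:
        raise ParameterError("local_align requires non-empty sequences")
    al = _aligner(match, mismatch, gap_open, gap_extend)
    score = al.score(target, query)
    if score <= 0:
        return EMPTY
    aln = al.align(target, query)[0]
    counts = aln.counts()
    matches = counts.identities
    length = counts.identities + counts.mismatches + counts.gaps
    tblocks, qblocks = aln.aligned
    return LocalAlignment(
        score=score,
        matches=matches,
        length=length,
        query_start=int(qblocks[0][0]),
        query_end=int(qblocks[-1][1]),
        target_start=int(tblocks[0][0]),
        target_end=int(tblocks[-1][1]),
    )


def local_align_both_strands(query: str, target: str, **kw) -> LocalAlignment:
    """Best of aligning ``query`` and its reverse complement against ``target``.

    Minus-strand coordinates are reported on the original (input) query.
    """
    fwd = local_align(query, target, **kw)
    rc = local_align(revcomp(query), target, **kw)
    if rc.score > fwd.score:
        n = len(query)
        return LocalAlignment(rc.score, rc.matches, rc.length,
                              n - rc.query_end, n - rc.query_start,
                              rc.target_start, rc.target_end, strand="-")
    return fwd


@dataclass(slots=True)
class LibraryHit:
    element: str
    alignment: LocalAlignment


def best_library_hit(query: str, library: dict[str, str], *,
                     min_identity: float = 0.0, min_length: int = 0,
                     both_strands: bool = True) -> LibraryHit | None:
    """Highest-scoring hit of ``query`` against a dict of element sequences.

    Returns ``None`` when no hit passes the identity/length thresholds.  The
    best hit is chosen by score; thresholds are then applied to it.  A
    query contained verbatim in an element short-circuits (it is the maximal
    possible score); otherwise elements are ranked score-only and a single
    traceback is done for the winner.
    """
    if not library:
        raise ParameterError("library must not be empty")
    if len(query) >= min_length:
        rc = revcomp(query) if both_strands else None
        for name in sorted(library):
            seq = library[name]
            i = seq.find(query)
            if i != -1:
                return LibraryHit(name, LocalAlignment(
                    float(len(query)), len(query), len(query),
                    0, len(query), i, i + len(query), "+"))
            if rc is not None:
                i = seq.find(rc)
                if i != -1:
                    return LibraryHit(name, LocalAlignment(
                        float(len(query)), len(query), len(query),
                        0, len(query), i, i + len(query), "-"))
    al = _aligner(MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
    rc = revcomp(query)
    best_name, best_score = None, -1.0
    for name, seq in library.items():
        s = al.score(seq, query)
        if both_strands:
            s = max(s, al.score(seq, rc))
        if s > best_score:
            best_name, best_score = name, s
    assert best_name is not None
    aln = (local_align_both_strands(query, library[best_name]) if both_strands
           else local_align(query, library[best_name]))
    if aln.empty or aln.identity < min_identity or aln.length < min_length:
        return None
    return LibraryHit(best_name, aln)
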