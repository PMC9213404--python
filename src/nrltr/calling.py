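"""Breakpoint calling: anchor clustering, filter levels, merging and TSDs.

Anchors are clustered by single-linkage within an insert-size window; a
cluster becomes a candidate call when it carries enough supporting reads.
Each call gets a tiered evidence score ("filter level", 5 plus up to three
bonuses), nearby duplicate calls are merged keeping the best, and the 4-5 bp
target-site duplication is read off the soft-clip stacks flanking the
breakpoint: reads clipped on their right end pile up at the last duplicated
base, reads clipped on their left at the first, and a true insertion leaves
the two modal boundaries overlapping by exactly the TSD length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .discovery import AnchorEvidence
from .errors import ParameterError
from .formats import AlignedRead, CallRecord


@dataclass(slots=True)
class CallingParams:
    min_support: int = 10
    merge_window: int = 500
    cluster_window: int = 420       # insert_mean + 2*insert_sd by default
    min_filter_level: int = 7
    max_depth: int = 10_000
    read_length: int = 150
    tsd_min_reads: int = 2          # reads required per clip stack mode
    tsd_search_window: int = 300    # clip reads considered around a call

    def __post_init__(self):
        for f in ("min_support", "merge_window", "cluster_window",
                  "min_filter_level", "max_depth", "read_length"):
            if getattr(self, f) <= 0:
                raise ParameterError(f"{f} must be positive")


@dataclass
class AnchorCluster:
    chrom: str
    fwd_anchors: list[AnchorEvidence]     # 5'-side (+ strand) evidence
    rev_anchors: list[AnchorEvidence]     # 3'-side (- strand) evidence

    @property
    def anchors(self) -> list[AnchorEvidence]:
        return self.fwd_anchors + self.rev_anchors

    @property
    def innermost_5p(self) -> int | None:
        return max((a.anchor_end_pos for a in self.fwd_anchors), default=None)

    @property
    def innermost_3p(self) -> int | None:
        return min((a.anchor_end_pos for a in self.rev_anchors), default=None)

    @property
    def interval(self) -> tuple[int, int]:
        """Innermost interval for two-sided clusters; full anchor span for
        one-sided clusters (whose spread is the only width information)."""
        if self.fwd_anchors and self.rev_anchors:
            lo, hi = sorted((self.innermost_5p, self.innermost_3p))
            return lo, hi
        pos = [a.anchor_end_pos for a in self.anchors]
        return min(pos), max(pos)

    @property
    def width(self) -> int:
        lo, hi = self.interval
        return hi - lo


def cluster_anchors(anchors: Sequence[AnchorEvidence],
                    params: CallingParams | None = None) -> list[AnchorCluster]:
    """Single-linkage clustering of position-sorted anchors.

    Consecutive anchors on one chromosome chain into a cluster while their
    gap stays within ``cluster_window``; clusters deeper than ``max_depth``
    anchors are dropped (pile-up regions).
    """
    params = params or CallingParams()
    clusters: list[AnchorCluster] = []
    current: list[AnchorEvidence] = []

    def flush():
        if current and len(current) <= params.max_depth:
            clusters.append(AnchorCluster(
                chrom=current[0].chrom,
                fwd_anchors=[a for a in current if a.side_hint == "5p"],
                rev_anchors=[a for a in current if a.side_hint == "3p"]))

    for a in sorted(anchors, key=lambda a: (a.chrom, a.anchor_end_pos)):
        if (current and (a.chrom != current[-1].chrom
                         or a.anchor_end_pos - current[-1].anchor_end_pos
                         > params.cluster_window)):
            flush()
            current = []
        current.append(a)
    flush()
    return clusters


def call_breakpoint(cluster: AnchorCluster,
                    params: CallingParams | None = None) -> CallRecord | None:
    """Candidate call from a cluster, or None below ``min_support``.

    The breakpoint is the midpoint between the innermost 5'-side anchor end
    and the innermost 3'-side anchor start (the single side's innermost end
    for one-sided clusters).
    """
    params = params or CallingParams()
    s5 = len(cluster.fwd_anchors)
    s3 = len(cluster.rev_anchors)
    if s5 + s3 < params.min_support:
        return None
    if s5 and s3:
        bp = (cluster.innermost_5p + cluster.innermost_3p) // 2
    elif s5:
        bp = cluster.innermost_5p
    else:
        bp = cluster.innermost_3p
    return CallRecord(chrom=cluster.chrom, breakpoint_pos=bp,
                      support_5p=s5, support_3p=s3, filter_level=5)


def assign_filter_level(call: CallRecord, cluster: AnchorCluster,
                        clip_positions: Iterable[int],
                        params: CallingParams | None = None) -> int:
    """Evidence tier 5-8: base 5 plus one bonus each for two-sided support,
    a soft-clip stack abutting the breakpoint, and a tight cluster interval."""
    params = params or CallingParams()
    level = 5
    if len(cluster.fwd_anchors) >= 2 and len(cluster.rev_anchors) >= 2:
        level += 1
    near = sum(1 for p in clip_positions
               if abs(p - call.breakpoint_pos) <= 10)
    if near >= 2:
        level += 1
    if cluster.width <= 2 * params.read_length:
        level += 1
    return level


def merge_calls(calls: Sequence[CallRecord],
                params: CallingParams | None = None) -> list[CallRecord]:
    """Collapse chains of calls within ``merge_window`` bp, keeping the best.

    Within each chain the winner has the highest (filter_level, total
    support), ties broken by leftmost position; the others are duplicates of
    the same insertion and are dropped.
    """
    params = params or CallingParams()
    out: list[CallRecord] = []
    chain: list[CallRecord] = []

    def flush():
        if chain:
            best = max(chain, key=lambda c: (c.filter_level, c.total_support,
                                             -c.breakpoint_pos))
            out.append(best)

    for c in sorted(calls, key=lambda c: (c.chrom, c.breakpoint_pos)):
        if (chain and (c.chrom != chain[-1].chrom
                       or c.breakpoint_pos - chain[-1].breakpoint_pos
                       > params.merge_window)):
            flush()
            chain = []
        chain.append(c)
    flush()
    return out


@dataclass(slots=True)
class TsdResult:
    """A detected target-site duplication (1-based inclusive interval)."""

    tsd_start: int
    tsd_end: int
    tsd_seq: str
    support_left: int        # right-clipped reads at the 5' boundary
    support_right: int       # left-clipped reads at the 3' boundary

    @property
    def length(self) -> int:
        return self.tsd_end - self.tsd_start + 1

    @property
    def midpoint(self) -> int:
        return (self.tsd_start + self.tsd_end) // 2


def detect_tsd(call: CallRecord, clip_reads: Iterable[AlignedRead],
               reference: dict[str, str],
               params: CallingParams | None = None,
               min_clip: int = 10) -> TsdResult | None:
    """Read the TSD off the two soft-clip stacks flanking a breakpoint.

    L = modal rightmost aligned position among right-clipped reads (the 5'
    stack), R = modal leftmost aligned position among left-clipped reads
    (the 3' stack); a 4-5 bp overlap L - R + 1 is a TSD and its sequence is
    taken from the reference (never from read bases).  Each mode needs
    ``tsd_min_reads`` supporting reads; among candidate (L, R) pairs the one
    with most support wins, then the shorter, then the leftmost.
    """
    params = params or CallingParams()
    right_stack: Counter[int] = Counter()
    left_stack: Counter[int] = Counter()
    for r in clip_reads:
        if not r.is_mapped or r.chrom != call.chrom:
            continue
        if abs(r.pos - call.breakpoint_pos) > params.tsd_search_window and \
           abs(r.end - call.breakpoint_pos) > params.tsd_search_window:
            continue
        if r.clip_right >= min_clip:
            right_stack[r.end] += 1
        if r.clip_left >= min_clip:
            left_stack[r.pos] += 1
    ls = [(p, n) for p, n in right_stack.items() if n >= params.tsd_min_reads]
    rs = [(p, n) for p, n in left_stack.items() if n >= params.tsd_min_reads]
    best: tuple | None = None
    for L, nl in ls:
        for R, nr in rs:
            span = L - R + 1
            if span not in (4, 5):
                continue
            key = (nl + nr, -span, -R)
            if best is None or key > best[0]:
                best = (key, L, R, nl, nr)
    if best is None:
        return None
    _, L, R, nl, nr = best
    seq = reference[call.chrom][R - 1: L]
    return TsdResult(tsd_start=R, tsd_end=L, tsd_seq=seq,
                     support_left=nl, support_right=nr)


def attach_tsd(call: CallRecord, tsd: TsdResult | None) -> CallRecord:
    """A copy of ``call`` with TSD fields filled in (no-op when tsd is None)."""
    if tsd is None:
        return call
    return replace(call, tsd_start=tsd.tsd_start, tsd_end=tsd.tsd_end,
                   tsd_seq=tsd.tsd_seq)
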