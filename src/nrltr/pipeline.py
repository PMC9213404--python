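"""End-to-end orchestration: discover -> call -> assemble -> classify.

``run_pipeline`` ties the stages together over in-memory read pairs (the CLI
layers file I/O on top).  Every stage is deterministic, so identical input
yields an identical call table and reconstruction set.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .assembly import (JunctionContig, ReconstructedLTR, analyze_junction,
                       assemble, extract_junction_reads, reconstruct_ltr)
from .calling import (AnchorCluster, CallingParams, TsdResult, attach_tsd,
                      assign_filter_level, call_breakpoint, cluster_anchors,
                      detect_tsd, merge_calls)
from .classify import SubtypeCall, classify_subtype
from .discovery import AnchorEvidence, DiscoveryParams, collect_anchors
from .formats import AlignedRead, CallRecord


def _as_tuples(pairs: Iterable) -> list[tuple[AlignedRead, AlignedRead]]:
    out = []
    for p in pairs:
        if isinstance(p, tuple):
            out.append(p)
        else:                       # SimPair-like
            out.append((p.r1, p.r2))
    return out


class PairIndex:
    """Coordinate index over mapped reads for fast windowed retrieval."""

    def __init__(self, pairs: Sequence[tuple[AlignedRead, AlignedRead]]):
        self.pairs = pairs
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, (r1, r2) in enumerate(pairs):
            for r in (r1, r2):
                if r.is_mapped and r.chrom is not None:
                    per_chrom.setdefault(r.chrom, []).append((r.pos, r.end, i))
        self._pos: dict[str, list[int]] = {}
        self._entries: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, entries in per_chrom.items():
            entries.sort()
            self._entries[chrom] = entries
            self._pos[chrom] = [e[0] for e in entries]

    def pair_ids_near(self, chrom: str, lo: int, hi: int,
                      max_read_span: int = 400) -> list[int]:
        entries = self._entries.get(chrom)
        if not entries:
            return []
        pos = self._pos[chrom]
        a = bisect_left(pos, lo - max_read_span)
        b = bisect_right(pos, hi)
        ids = {e[2] for e in entries[a:b] if e[1] >= lo}
        return sorted(ids)

    def pairs_near(self, chrom: str, lo: int, hi: int) -> list[tuple[AlignedRead, AlignedRead]]:
        return [self.pairs[i] for i in self.pair_ids_near(chrom, lo, hi)]

    def reads_near(self, chrom: str, lo: int, hi: int) -> list[AlignedRead]:
        out = []
        for r1, r2 in self.pairs_near(chrom, lo, hi):
            for r in (r1, r2):
                if r.is_mapped and r.chrom == chrom and r.pos <= hi and r.end >= lo:
                    out.append(r)
        return out


@dataclass
class LocusResult:
    """Everything the pipeline derived for one kept call."""

    call: CallRecord
    tsd: TsdResult | None
    junction_5p: JunctionContig | None
    junction_3p: JunctionContig | None
    reconstruction: ReconstructedLTR | None
    subtype: SubtypeCall | None


@dataclass
class PipelineResult:
    anchors: list[AnchorEvidence]
    calls_raw: list[CallRecord]       # per-cluster calls, pre-merge
    calls: list[CallRecord]           # merged calls at >= min_filter_level
    flagged: list[CallRecord]         # merged calls below min_filter_level
    loci: list[LocusResult]

    @property
    def reconstructions(self) -> list[ReconstructedLTR | None]:
        return [l.reconstruction for l in self.loci]


def _cap_reads(reads: list[str], max_reads: int) -> list[str]:
    if len(reads) <= max_reads:
        return reads
    idx = np.unique(np.linspace(0, len(reads) - 1, max_reads).round().astype(int))
    return [reads[i] for i in idx]


def _pick_junction(contigs, reference, call, library, side: str,
                   min_identity: float, tsd=None) -> JunctionContig | None:
    for contig in contigs:
        j = analyze_junction(contig, reference, call, library,
                             min_identity=min_identity, tsd=tsd)
        if j is not None and j.junction_side == side:
            return j
    return None


def run_pipeline(pairs: Iterable, reference: dict[str, str],
                 library: dict[str, str],
                 discovery_params: DiscoveryParams | None = None,
                 calling_params: CallingParams | None = None,
                 *, junction_window: int = 150, max_side_reads: int = 120,
                 min_junction_identity: float = 0.80,
                 classify_subtypes: bool = True) -> PipelineResult:
    """Run discovery, calling, assembly and classification over read pairs.

    ``pairs`` may be ``(read1, read2)`` tuples or simulator pair objects;
    ``library`` is the LTR element library the evidence is matched against.
    """
    dparams = discovery_params or DiscoveryParams()
    cparams = calling_params or CallingParams(
        cluster_window=dparams.insert_mean + 2 * dparams.insert_sd)
    tuples = _as_tuples(pairs)
    anchors = collect_anchors(tuples, library, dparams)
    clusters = cluster_anchors(anchors, cparams)
    index = PairIndex(tuples)

    calls_raw: list[CallRecord] = []
    cluster_of: dict[tuple[str, int], AnchorCluster] = {}
    for cluster in clusters:
        call = call_breakpoint(cluster, cparams)
        if call is None:
            continue
        nearby = index.reads_near(call.chrom,
                                  call.breakpoint_pos - cparams.tsd_search_window,
                                  call.breakpoint_pos + cparams.tsd_search_window)
        clip_positions = ([r.end for r in nearby if r.clip_right >= 10]
                          + [r.pos for r in nearby if r.clip_left >= 10])
        level = assign_filter_level(call, cluster, clip_positions, cparams)
        call = replace(call, filter_level=level)
        calls_raw.append(call)
        cluster_of[(call.chrom, call.breakpoint_pos)] = cluster

    merged = merge_calls(calls_raw, cparams)
    kept = [c for c in merged if c.filter_level >= cparams.min_filter_level]
    flagged = [c for c in merged if c.filter_level < cparams.min_filter_level]

    loci: list[LocusResult] = []
    final_calls: list[CallRecord] = []
    for call in kept:
        clip_reads = index.reads_near(call.chrom,
                                      call.breakpoint_pos - cparams.tsd_search_window,
                                      call.breakpoint_pos + cparams.tsd_search_window)
        tsd = detect_tsd(call, clip_reads, reference, cparams)
        call = attach_tsd(call, tsd)
        center = tsd.midpoint if tsd else call.breakpoint_pos
        cand = index.pairs_near(call.chrom, center - junction_window - 100,
                                center + junction_window + 100)
        s5, s3 = extract_junction_reads(cand, call.chrom, center,
                                        window=junction_window)
        contigs5 = assemble(_cap_reads(s5, max_side_reads)) if s5 else []
        contigs3 = assemble(_cap_reads(s3, max_side_reads)) if s3 else []
        j5 = _pick_junction(contigs5, reference, call, library, "5p",
                            min_junction_identity, tsd)
        if j5 is None:
            j5 = _pick_junction(contigs3, reference, call, library, "5p",
                                min_junction_identity, tsd)
        j3 = _pick_junction(contigs3, reference, call, library, "3p",
                            min_junction_identity, tsd)
        if j3 is None:
            j3 = _pick_junction(contigs5, reference, call, library, "3p",
                                min_junction_identity, tsd)
        rec = reconstruct_ltr(call, j5, j3, tsd)
        subtype = None
        if rec is not None:
            call = replace(call, status="LTR")
            if classify_subtypes and rec.completeness == "both":
                subtype = classify_subtype(rec.ltr_seq)
        else:
            call = replace(call, status="non-LTR")
        final_calls.append(call)
        loci.append(LocusResult(call=call, tsd=tsd, junction_5p=j5,
                                junction_3p=j3, reconstruction=rec,
                                subtype=subtype))
    return PipelineResult(anchors=anchors, calls_raw=calls_raw,
                          calls=final_calls, flagged=flagged, loci=loci)
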