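"""Read-pair classification and anchor-evidence collection.

The discovery stage scans aligned read pairs for mapping anomalies that
betray a non-reference insertion: singletons and discordant pairs whose
unanchored mate matches the LTR element library, and soft-clipped reads
whose clipped tail does.  Each qualifying read yields an
:class:`AnchorEvidence` locating the insertion near the anchor's inner end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .align import best_library_hit
from .errors import PairingError, ParameterError
from .formats import AlignedRead

PAIR_CLASSES = ("proper", "discordant", "singleton", "soft_clipped",
                "unmapped_pair")


@dataclass(slots=True)
class DiscoveryParams:
    """Thresholds for pair classification and library matching.

    ``min_identity``/``min_hit_length`` mirror the published defaults of the
    discordant-mate discovery tools this stage re-implements; clip hits only
    need ``min_clip`` bases because a clipped tail is positionally exact.
    """

    insert_mean: int = 350
    insert_sd: int = 35
    proper_span_k: float = 3.0
    min_identity: float = 0.80
    min_hit_length: int = 36
    min_mapq: int = 20
    min_clip: int = 10

    def __post_init__(self):
        for f in ("insert_mean", "insert_sd", "proper_span_k",
                  "min_identity", "min_hit_length", "min_mapq", "min_clip"):
            if getattr(self, f) is None or getattr(self, f) <= 0:
                if f == "min_mapq" and self.min_mapq == 0:
                    continue
                raise ParameterError(f"{f} must be positive")

    @property
    def span_lo(self) -> float:
        return self.insert_mean - self.proper_span_k * self.insert_sd

    @property
    def span_hi(self) -> float:
        return self.insert_mean + self.proper_span_k * self.insert_sd


def classify_pair(r1: AlignedRead, r2: AlignedRead,
                  params: DiscoveryParams) -> str:
    """One of proper / discordant / singleton / soft_clipped / unmapped_pair.

    Soft-clip evidence takes precedence over the proper-span predicate; a
    pair is proper when both mates map to one chromosome in FR orientation
    with an outer span inside ``insert_mean ± k·insert_sd``.
    """
    if r1 is None or r2 is None:
        raise PairingError("classify_pair needs both mates")
    m1, m2 = r1.is_mapped, r2.is_mapped
    if not m1 and not m2:
        return "unmapped_pair"
    if m1 != m2:
        return "singleton"
    if max(r1.clip_left, r1.clip_right, r2.clip_left, r2.clip_right) >= params.min_clip:
        return "soft_clipped"
    if r1.chrom == r2.chrom and r1.is_reverse != r2.is_reverse:
        fwd, rev = (r1, r2) if not r1.is_reverse else (r2, r1)
        if fwd.pos <= rev.pos:
            span = max(r1.end, r2.end) - min(r1.pos, r2.pos) + 1
            if params.span_lo <= span <= params.span_hi:
                return "proper"
    return "discordant"


@dataclass(slots=True)
class AnchorEvidence:
    """A mapped read locating an insertion via its mate or clipped tail."""

    chrom: str
    anchor_end_pos: int       # 1-based inner end of the anchor
    anchor_strand: str        # "+" | "-"
    evidence_kind: str        # "mate_hit" | "clip_hit"
    library_element: str
    hit_identity: float
    hit_length: int
    side_hint: str            # "5p" | "3p"


def _mate_evidence(anchor: AlignedRead, mate_seq: str, library: dict[str, str],
                   params: DiscoveryParams) -> AnchorEvidence | None:
    hit = best_library_hit(mate_seq, library, min_identity=params.min_identity,
                           min_length=params.min_hit_length)
    if hit is None:
        return None
    if anchor.is_reverse:
        pos, side, strand = anchor.pos, "3p", "-"
    else:
        pos, side, strand = anchor.end, "5p", "+"
    return AnchorEvidence(anchor.chrom, pos, strand, "mate_hit", hit.element,
                          hit.alignment.identity, hit.alignment.length, side)


def _clip_evidence(read: AlignedRead, library: dict[str, str],
                   params: DiscoveryParams) -> list[AnchorEvidence]:
    out = []
    strand = "-" if read.is_reverse else "+"
    if read.clip_right >= params.min_clip:
        tail = read.seq[-read.clip_right:]
        hit = best_library_hit(tail, library, min_identity=params.min_identity,
                               min_length=params.min_clip)
        if hit is not None:
            out.append(AnchorEvidence(read.chrom, read.end, strand, "clip_hit",
                                      hit.element, hit.alignment.identity,
                                      hit.alignment.length, "5p"))
    if read.clip_left >= params.min_clip:
        tail = read.seq[:read.clip_left]
        hit = best_library_hit(tail, library, min_identity=params.min_identity,
                               min_length=params.min_clip)
        if hit is not None:
            out.append(AnchorEvidence(read.chrom, read.pos, strand, "clip_hit",
                                      hit.element, hit.alignment.identity,
                                      hit.alignment.length, "3p"))
    return out


def collect_anchors(pairs: Iterable[tuple[AlignedRead, AlignedRead]],
                    library: dict[str, str],
                    params: DiscoveryParams | None = None) -> list[AnchorEvidence]:
    """Anchor evidence from every informative (non-proper) read pair.

    Singleton and discordant pairs contribute mate hits (the unanchored
    mate aligned to every library element on both strands); any sufficiently
    clipped read in a non-proper pair contributes clip hits.  Proper,
    unclipped pairs never yield evidence.
    """
    if not library:
        raise ParameterError("element library must not be empty")
    params = params or DiscoveryParams()
    evidence: list[AnchorEvidence] = []
    for r1, r2 in pairs:
        cls = classify_pair(r1, r2, params)
        if cls in ("proper", "unmapped_pair"):
            continue
        if cls == "singleton":
            anchor, mate = (r1, r2) if r1.is_mapped else (r2, r1)
            if anchor.mapq >= params.min_mapq:
                ev = _mate_evidence(anchor, mate.seq, library, params)
                if ev:
                    evidence.append(ev)
                evidence.extend(_clip_evidence(anchor, library, params))
        elif cls == "discordant":
            for anchor, mate in ((r1, r2), (r2, r1)):
                if anchor.is_mapped and anchor.mapq >= params.min_mapq:
                    ev = _mate_evidence(anchor, mate.seq, library, params)
                    if ev:
                        evidence.append(ev)
        else:  # soft_clipped
            for read in (r1, r2):
                if read.is_mapped and read.mapq >= params.min_mapq:
                    evidence.extend(_clip_evidence(read, library, params))
    evidence.sort(key=lambda e: (e.chrom, e.anchor_end_pos, e.side_hint,
                                 e.evidence_kind, e.library_element))
    return evidence


_ANCHOR_COLUMNS = ["chrom", "pos", "strand", "kind", "element",
                   "identity", "length", "side"]


def write_anchors(anchors: Sequence[AnchorEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# nrltr anchor table; pos 1-based\n")
        fh.write("#" + "\t".join(_ANCHOR_COLUMNS) + "\n")
        for a in anchors:
            fh.write(f"{a.chrom}\t{a.anchor_end_pos}\t{a.anchor_strand}\t"
                     f"{a.evidence_kind}\t{a.library_element}\t"
                     f"{a.hit_identity:.4f}\t{a.hit_length}\t{a.side_hint}\n")


def read_anchors(path: str | Path) -> list[AnchorEvidence]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            out.append(AnchorEvidence(p[0], int(p[1]), p[2], p[3], p[4],
                                      float(p[5]), int(p[6]), p[7]))
    return out
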