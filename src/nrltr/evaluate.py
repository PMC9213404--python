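"""Scoring pipeline output against planted truth, and locus-table summaries.

``evaluate`` matches calls to the synthetic ground truth one-to-one by
breakpoint distance and reports precision/recall, TSD exactness and
reconstruction identity.  ``summarize_loci`` merges per-sample call lists
into the locus-by-sample table layout used to report non-reference element
surveys across individuals: one row per merged locus, one status cell per
sample, rows partitioned into loci confirmed with both TSDs versus a single
TSD.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .align import local_align
from .assembly import ReconstructedLTR
from .errors import ParameterError
from .formats import CallRecord
from .simulate import TruthRecord


def _identity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    aln = local_align(a, b)
    return aln.matches / max(len(a), len(b))


@dataclass
class EvalReport:
    n_truth: int
    n_called: int
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float | None          # None when no calls were made (0/0)
    recall: float
    f1: float | None
    tsd_exact_rate: float | None     # over matched calls
    ltr_identity_mean: float | None  # over matched calls with reconstructions
    completeness_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_truth", "n_called", "true_positives", "false_positives",
            "false_negatives", "precision", "recall", "f1",
            "tsd_exact_rate", "ltr_identity_mean", "completeness_counts")}


def evaluate(calls: Sequence[CallRecord],
             reconstructions: Sequence[ReconstructedLTR | None],
             truth: Sequence[TruthRecord],
             tolerance_bp: int = 10) -> EvalReport:
    """Greedy one-to-one matching of calls to truth by breakpoint distance.

    A call is a true positive when its breakpoint lies within
    ``tolerance_bp`` of a truth insertion position (the first duplicated
    base).  TSD exactness requires the called interval and sequence to equal
    the planted target site; reconstruction identity compares against the
    planted TSD-to-TSD sequence.
    """
    if len(reconstructions) not in (0, len(calls)):
        raise ParameterError("reconstructions must parallel calls")
    recs = list(reconstructions) or [None] * len(calls)
    cand = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(calls):
            if c.chrom != t.chrom:
                continue
            d = abs(c.breakpoint_pos - t.position)
            if d <= tolerance_bp:
                cand.append((d, t.position, c.breakpoint_pos, ti, ci))
    cand.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    matches: list[tuple[int, int]] = []
    for d, _, _, ti, ci in cand:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matches.append((ti, ci))
    tp = len(matches)
    fp = len(calls) - tp
    fn = len(truth) - tp
    precision = tp / len(calls) if calls else None
    recall = tp / len(truth) if truth else 1.0
    f1 = None
    if precision is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)

    tsd_exact = None
    identities = []
    completeness: Counter[str] = Counter()
    if matches:
        n_exact = 0
        for ti, ci in matches:
            t, c = truth[ti], calls[ci]
            if (c.has_tsd and c.tsd_start == t.position
                    and c.tsd_seq == t.tsd_sequence):
                n_exact += 1
            rec = recs[ci]
            if rec is not None:
                identities.append(_identity(rec.sequence,
                                            t.expected_reconstruction))
                completeness[rec.completeness] += 1
        tsd_exact = n_exact / len(matches)
    return EvalReport(
        n_truth=len(truth), n_called=len(calls), true_positives=tp,
        false_positives=fp, false_negatives=fn, precision=precision,
        recall=recall, f1=f1, tsd_exact_rate=tsd_exact,
        ltr_identity_mean=(sum(identities) / len(identities)
                           if identities else None),
        completeness_counts=dict(completeness))


# ==========================================================================
# Locus-by-sample summary
# ==========================================================================


@dataclass(slots=True)
class LocusObservation:
    """One sample's finding at one locus."""

    chrom: str
    pos: int
    status: str               # LTR / PERV-A / PERV-B / PERV-C / non-LTR
    both_tsd: bool


@dataclass
class LocusRow:
    chrom: str
    pos: int
    statuses: dict[str, str]
    both_tsd: bool


@dataclass
class LocusTable:
    samples: list[str]
    rows_both: list[LocusRow]
    rows_single: list[LocusRow]

    @property
    def n_both_tsd(self) -> int:
        return len(self.rows_both)

    @property
    def n_single_tsd(self) -> int:
        return len(self.rows_single)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for section, rows in (("both_tsd", self.rows_both),
                              ("single_tsd", self.rows_single)):
            for r in rows:
                rec = {"chrom": r.chrom, "pos": r.pos, "section": section}
                for s in self.samples:
                    rec[s] = r.statuses.get(s, "non-LTR")
                recs.append(rec)
        return pd.DataFrame(recs)


def _chrom_key(chrom: str):
    digits = "".join(c for c in chrom if c.isdigit())
    return (0, int(digits)) if digits else (1, chrom)


def summarize_loci(per_sample: dict[str, Sequence[LocusObservation]],
                   merge_window: int = 500) -> LocusTable:
    """Merge per-sample loci (within ``merge_window`` bp) into table rows.

    Samples without a finding at a merged locus are filled in as "non-LTR";
    a row lands in the both-TSD section when any sample observed the locus
    with both TSD copies.
    """
    if not per_sample:
        raise ParameterError("summarize_loci needs at least one sample")
    samples = list(per_sample)
    all_obs: list[tuple[str, int, str, LocusObservation]] = []
    for s, obs in per_sample.items():
        for o in obs:
            all_obs.append((o.chrom, o.pos, s, o))
    all_obs.sort(key=lambda t: (_chrom_key(t[0]), t[1], t[2]))
    rows: list[LocusRow] = []
    chain: list[tuple[str, int, str, LocusObservation]] = []

    def flush():
        if not chain:
            return
        statuses: dict[str, str] = {}
        for _, _, s, o in chain:
            if s not in statuses or statuses[s] == "non-LTR":
                statuses[s] = o.status
        rows.append(LocusRow(
            chrom=chain[0][0], pos=min(p for _, p, _, _ in chain),
            statuses={s: statuses.get(s, "non-LTR") for s in samples},
            both_tsd=any(o.both_tsd for _, _, _, o in chain)))

    for item in all_obs:
        if chain and (item[0] != chain[-1][0]
                      or item[1] - chain[-1][1] > merge_window):
            flush()
            chain = []
        chain.append(item)
    flush()
    return LocusTable(samples=samples,
                      rows_both=[r for r in rows if r.both_tsd],
                      rows_single=[r for r in rows if not r.both_tsd])


# ==========================================================================
# Worked-example locus table (three Vietnamese native pig genomes)
# ==========================================================================


def load_vnp_locus_table() -> tuple[dict[str, list[LocusObservation]], pd.DataFrame]:
    """The packaged locus-by-sample table for three Vietnamese native pig
    genomes (samples VnP1-VnP3) surveyed for non-reference PERV-LTR loci.

    Returns per-sample observation lists (ready for :func:`summarize_loci`)
    together with the raw table as a DataFrame.
    """
    path = resources.files("nrltr").joinpath("data/vnp_tsd_loci.tsv")
    df = pd.read_csv(path, sep="\t", comment=None)
    samples = ["VnP1", "VnP2", "VnP3"]
    per_sample: dict[str, list[LocusObservation]] = {s: [] for s in samples}
    for _, row in df.iterrows():
        for s in samples:
            per_sample[s].append(LocusObservation(
                chrom=row["chrom"], pos=int(row["pos"]),
                status=row[s], both_tsd=bool(row["both_tsd"])))
    return per_sample, df
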