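"""Readers and writers for every on-disk artifact the pipeline touches.

Conventions
-----------
* FASTA / FASTQ / text SAM are the native formats (BAM can be converted
  externally with ``samtools view -h``).
* All tables are tab-separated with a ``#``-prefixed header line; genomic
  positions in tables are 1-based inclusive, BED output is 0-based half-open.
* Sequences are uppercased on input; IUPAC ambiguity codes are accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, PairingError
from .util import IUPAC

# --------------------------------------------------------------------------
# FASTA / FASTQ
# --------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict.

    Duplicate names and non-IUPAC characters are rejected; sequences are
    uppercased.  An empty file yields an empty dict.
    """
    out: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}", i)
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC
        if bad:
            raise FormatError(
                f"non-IUPAC characters {sorted(bad)} in record {rec.id!r}", i)
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def write_fastq_pair(pairs: Iterable[tuple[str, str, str]],
                     path1: str | Path, path2: str | Path,
                     quality_char: str = "I") -> None:
    """Write paired reads as two FASTQ files with ``/1`` and ``/2`` suffixes.

    ``pairs`` yields ``(name, seq1, seq2)`` with sequences already in
    sequencing orientation.
    """
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, s2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{quality_char * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{quality_char * len(s2)}\n")


# --------------------------------------------------------------------------
# SAM
# --------------------------------------------------------------------------

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@lru_cache(maxsize=65536)
def parse_cigar(cigar: str) -> tuple[tuple[int, str], ...]:
    if cigar == "*" or not cigar:
        return ()
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return tuple((int(n), o) for n, o in ops)


@dataclass(slots=True)
class AlignedRead:
    """A single SAM record with the fields the pipeline uses."""

    name: str
    flag: int
    chrom: str | None        # None when unmapped with no placement
    pos: int                 # 1-based leftmost aligned base; 0 when unmapped
    mapq: int
    cigar: str               # '*' when unmapped
    seq: str
    mate_chrom: str | None = None
    mate_pos: int = 0
    tlen: int = 0

    # -- flag helpers -------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def mate_mapped(self) -> bool:
        return not self.flag & FLAG_MATE_UNMAPPED

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def mate_reverse(self) -> bool:
        return bool(self.flag & FLAG_MATE_REVERSE)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)

    @property
    def is_proper_flag(self) -> bool:
        return bool(self.flag & FLAG_PROPER)

    # -- CIGAR helpers ------------------------------------------------
    @property
    def cigar_ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.cigar)

    @property
    def clip_left(self) -> int:
        ops = self.cigar_ops
        return ops[0][0] if ops and ops[0][1] in "SH" else 0

    @property
    def clip_right(self) -> int:
        ops = self.cigar_ops
        return ops[-1][0] if ops and ops[-1][1] in "SH" else 0

    @property
    def ref_span(self) -> int:
        return sum(n for n, o in self.cigar_ops if o in _REF_OPS)

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        return self.pos + self.ref_span - 1

    def validate(self, record_no: int | None = None) -> None:
        if self.is_mapped and self.cigar != "*" and self.seq != "*":
            qlen = sum(n for n, o in self.cigar_ops if o in _QUERY_OPS)
            if qlen != len(self.seq):
                raise FormatError(
                    f"CIGAR {self.cigar} consumes {qlen} bases but sequence "
                    f"is {len(self.seq)} bp for read {self.name!r}", record_no)


def _from_pysam(seg: pysam.AlignedSegment, header: pysam.AlignmentHeader) -> AlignedRead:
    chrom = seg.reference_name if seg.reference_id >= 0 else None
    mate_chrom = seg.next_reference_name if seg.next_reference_id >= 0 else None
    return AlignedRead(
        name=seg.query_name,
        flag=seg.flag,
        chrom=chrom,
        pos=(seg.reference_start + 1) if seg.reference_start is not None and seg.reference_start >= 0 else 0,
        mapq=seg.mapping_quality,
        cigar=seg.cigarstring or "*",
        seq=seg.query_sequence or "*",
        mate_chrom=mate_chrom,
        mate_pos=(seg.next_reference_start + 1) if seg.next_reference_start is not None and seg.next_reference_start >= 0 else 0,
        tlen=seg.template_length,
    )


def read_sam(path: str | Path, reference_names: Iterable[str] | None = None) -> list[AlignedRead]:
    """Read a text SAM file, validating each record.

    When ``reference_names`` is given, the header ``@SQ`` names are checked
    against it.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if reference_names is not None:
            missing = set(fh.references) - set(reference_names)
            if missing:
                raise FormatError(f"SAM header @SQ names {sorted(missing)} absent "
                                  "from the reference")
        i = 0
        it = iter(fh)
        while True:
            try:
                seg = next(it)
            except StopIteration:
                break
            except (OSError, ValueError) as exc:
                raise FormatError(f"unparseable SAM record: {exc}", i + 1) from exc
            i += 1
            read = _from_pysam(seg, fh.header)
            read.validate(record_no=i)
            reads.append(read)
    return reads


def iter_pairs(reads: Iterable[AlignedRead], strict: bool = True) -> Iterator[tuple[AlignedRead, AlignedRead]]:
    """Reunite mates by name; yields ``(read1, read2)`` tuples.

    With ``strict`` a read whose mate never appears raises
    :class:`PairingError`.
    """
    pending: dict[str, AlignedRead] = {}
    for r in reads:
        other = pending.pop(r.name, None)
        if other is None:
            pending[r.name] = r
        else:
            first, second = (other, r) if other.is_read1 else (r, other)
            yield first, second
    if pending and strict:
        raise PairingError(f"{len(pending)} reads without a mate "
                           f"(e.g. {next(iter(pending))!r})")


def write_sam(reads: Iterable[AlignedRead], ref_lengths: dict[str, int],
              path: str | Path) -> None:
    """Write records as text SAM with ``@SQ`` header lines."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": l} for n, l in ref_lengths.items()],
    })
    names = list(ref_lengths)
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.name
            seg.flag = r.flag
            seg.reference_id = tid[r.chrom] if r.chrom else -1
            seg.reference_start = r.pos - 1 if r.pos else -1
            seg.mapping_quality = r.mapq
            if r.cigar != "*":
                seg.cigarstring = r.cigar
            seg.next_reference_id = tid[r.mate_chrom] if r.mate_chrom else -1
            seg.next_reference_start = r.mate_pos - 1 if r.mate_pos else -1
            seg.template_length = r.tlen
            seg.query_sequence = r.seq if r.seq != "*" else None
            if r.seq != "*":
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            out.write(seg)


# --------------------------------------------------------------------------
# Call / TSD tables and BED
# --------------------------------------------------------------------------

CALL_STATUSES = {"LTR", "PERV-A", "PERV-B", "PERV-C", "non-LTR", "candidate"}


@dataclass(slots=True)
class CallRecord:
    """A candidate non-reference insertion locus."""

    chrom: str
    breakpoint_pos: int          # 1-based
    support_5p: int
    support_3p: int
    filter_level: int
    tsd_start: int | None = None  # 1-based inclusive
    tsd_end: int | None = None
    tsd_seq: str | None = None
    status: str = "candidate"

    def __post_init__(self):
        if not 1 <= self.filter_level <= 8:
            raise FormatError(f"filter level {self.filter_level} outside 1..8")
        tsd = (self.tsd_start, self.tsd_end, self.tsd_seq)
        present = [x is not None for x in tsd]
        if any(present) and not all(present):
            raise FormatError("TSD fields must be all present or all absent")
        if self.tsd_seq is not None and len(self.tsd_seq) not in (4, 5):
            raise FormatError(f"TSD length {len(self.tsd_seq)} outside 4..5")
        if self.status not in CALL_STATUSES:
            raise FormatError(f"unknown call status {self.status!r}")

    @property
    def has_tsd(self) -> bool:
        return self.tsd_seq is not None

    @property
    def total_support(self) -> int:
        return self.support_5p + self.support_3p


_CALL_COLUMNS = ["chrom", "breakpoint_pos", "support_5p", "support_3p",
                 "filter_level", "tsd_start", "tsd_end", "tsd_seq", "status"]


def _sorted_calls(records: Iterable[CallRecord]) -> list[CallRecord]:
    return sorted(records, key=lambda r: (r.chrom, r.breakpoint_pos))


def write_calls(records: Iterable[CallRecord], path: str | Path) -> None:
    """Tab-separated call table; positions 1-based inclusive (see header)."""
    with open(path, "w") as fh:
        fh.write("# nrltr call table; coordinates 1-based inclusive\n")
        fh.write("#" + "\t".join(_CALL_COLUMNS) + "\n")
        for r in _sorted_calls(records):
            fh.write("\t".join([
                r.chrom, str(r.breakpoint_pos), str(r.support_5p),
                str(r.support_3p), str(r.filter_level),
                str(r.tsd_start) if r.tsd_start is not None else ".",
                str(r.tsd_end) if r.tsd_end is not None else ".",
                r.tsd_seq if r.tsd_seq is not None else ".",
                r.status,
            ]) + "\n")


def read_calls(path: str | Path) -> list[CallRecord]:
    out: list[CallRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_CALL_COLUMNS):
                raise FormatError(f"expected {len(_CALL_COLUMNS)} columns, "
                                  f"got {len(parts)}", i)
            out.append(CallRecord(
                chrom=parts[0], breakpoint_pos=int(parts[1]),
                support_5p=int(parts[2]), support_3p=int(parts[3]),
                filter_level=int(parts[4]),
                tsd_start=None if parts[5] == "." else int(parts[5]),
                tsd_end=None if parts[6] == "." else int(parts[6]),
                tsd_seq=None if parts[7] == "." else parts[7],
                status=parts[8]))
    return out


def write_bed(records: Iterable[CallRecord], path: str | Path) -> None:
    """BED (0-based half-open) of TSD intervals for calls that have one."""
    with open(path, "w") as fh:
        for r in _sorted_calls(records):
            if r.has_tsd:
                fh.write(f"{r.chrom}\t{r.tsd_start - 1}\t{r.tsd_end}\t"
                         f"{r.tsd_seq}\n")


def write_ltr_fasta(reconstructions, path: str | Path) -> None:
    """FASTA of reconstructed LTRs; headers carry locus, completeness, length."""
    seqs = {}
    for rec in reconstructions:
        name = f"{rec.chrom}_{rec.position}|{rec.completeness}|{len(rec.sequence)}bp"
        seqs[name] = rec.sequence
    write_fasta(seqs, path)
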