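"""Small sequence helpers used throughout the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                            "TGCAYRMKVHDBNtgcayrmkvhdbn")

#: canonical nucleotide order used for deterministic tie-breaking
BASES = "ACGT"

IUPAC = set("ACGTRYSWKMBDHVN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    """IID random sequence with the requested expected GC fraction."""
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(BASES[i] for i in idx)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def seq_to_array(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3; anything else (gap, N) as 4."""
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
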