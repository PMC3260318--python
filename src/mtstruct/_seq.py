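"""Low-level sequence helpers shared across the package.

All coordinates in this package are 0-based half-open. On a circular
chromosome of length L a position is always reduced modulo L; an interval
may wrap the origin, in which case it is stored as (start, end) with
end < start and its length is end - start + L.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """View a DNA string as an uint8 array (ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    """Random circular-chromosome sequence with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return array_to_seq(BASES[codes])


def circ_slice(seq: str, start: int, end: int) -> str:
    """Substring of a circular sequence; wraps when end <= start.

    `start`/`end` are reduced modulo len(seq); start == end yields the
    full-length rotation starting at `start`.
    """
    n = len(seq)
    start %= n
    end %= n
    if start < end:
        return seq[start:end]
    return seq[start:] + seq[:end]


def interval_len(start: int, end: int, n: int) -> int:
    """Length of circular interval [start, end) on a circle of size n."""
    return (end - start) % n if (end - start) % n else (n if start == end else 0)


def circ_dist(a: int, b: int, n: int) -> int:
    """Shorter-arc distance between two positions on a circle of size n."""
    d = abs(a - b) % n
    return min(d, n - d)


def gc_content(seq: str) -> float:
    """GC percent of a sequence; ambiguous bases ignored in both terms."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return float("nan")
    return 100.0 * gc / (gc + at)


def at_content(seq: str) -> float:
    """AT percent of a sequence; ambiguous bases excluded from both
    numerator and denominator. Undefined (ValueError) on empty input."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if len(s) == 0:
        raise ValueError("AT content undefined for empty sequence")
    if gc + at == 0:
        return float("nan")
    return 100.0 * at / (gc + at)
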