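"""Read-pair mapping and consistency classification.

Placement is exact/near-exact: a handful of exact seeds per read nominate
candidate start positions, the full read is then scored by Hamming
distance against the (doubled, hence circular) chromosome sequence, and
the least-mismatch placement wins. Reads that place equally well at more
than one locus are *ambiguous* and excluded from every downstream count;
so are unmapped reads. Coordinates are reduced modulo chromosome length.

A deduplicated pair is **consistent** with the reference conformation iff
both ends map to one chromosome, face inward (one forward, one reverse
read), and their span — the circular arc from the forward read's start to
the reverse read's end — lies inside the library window (edges
inclusive). Everything else, including cross-chromosome pairs, is
**inconsistent**. PCR duplicates (identical mapping start positions for
both ends) are flagged before classification and excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import revcomp, seq_to_array
from .model import (
    AMBIGUOUS,
    CONSISTENT,
    DUPLICATE,
    INCONSISTENT,
    UNMAPPED,
    GenomeModel,
    LibraryWindow,
)


class ReadMapper:
    """Seeded exact/near-exact placement on a circular multichromosomal genome."""

    def __init__(
        self,
        genome: GenomeModel,
        seed_size: int = 20,
        max_mismatch_frac: float = 0.12,
    ):
        self.genome = genome
        self.k = seed_size
        self.max_mismatch_frac = max_mismatch_frac
        self.chrom_ids = list(genome.chromosomes)
        self.lengths = np.array([len(genome[c]) for c in self.chrom_ids])
        # doubled arrays allow any read starting in [0, L) to be compared
        # without wrapping logic
        self.arrays = [
            seq_to_array(genome[c].seq + genome[c].seq) for c in self.chrom_ids
        ]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ci, cid in enumerate(self.chrom_ids):
            s = genome[cid].seq
            d = s + s[: self.k - 1]
            for p in range(len(s)):
                self.index.setdefault(d[p : p + self.k], []).append((ci, p))

    def _candidates(self, seq: str) -> set[tuple[int, int]]:
        k = self.k
        offs = sorted({0, (len(seq) - k) // 2, len(seq) - k})
        cands: set[tuple[int, int]] = set()
        for off in offs:
            for ci, p in self.index.get(seq[off : off + k], ()):  # noqa: E203
                cands.add((ci, int((p - off) % self.lengths[ci])))
        return cands

    def map_read(self, seq: str) -> tuple:
        """Best placement of one read.

        Returns (chrom, pos, strand, mismatches) or (None, -1, '.', -1)
        for unmapped, or ('*', -1, '.', -1) for ambiguous (>=2 equally
        good distinct placements).
        """
        if len(seq) < self.k:
            return (None, -1, ".", -1)
        max_mm = max(2, int(np.ceil(self.max_mismatch_frac * len(seq))))
        best = None
        best_mm = max_mm + 1
        tie = False
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = seq_to_array(s)
            for ci, pos in self._candidates(s):
                g = self.arrays[ci][pos : pos + len(s)]
                if len(g) < len(s):
                    continue
                mm = int(np.count_nonzero(g != arr))
                if mm < best_mm:
                    best_mm = mm
                    best = (self.chrom_ids[ci], pos, strand)
                    tie = False
                elif mm == best_mm and best is not None:
                    if (self.chrom_ids[ci], pos, strand) != best:
                        tie = True
        if best is None or best_mm > max_mm:
            return (None, -1, ".", -1)
        if tie:
            return ("*", -1, ".", -1)
        return (best[0], best[1], best[2], best_mm)


def map_reads(
    reads1: list[tuple[str, str]],
    reads2: list[tuple[str, str]],
    genome: GenomeModel,
    mapper: ReadMapper | None = None,
) -> pd.DataFrame:
    """Map both ends of every pair; returns the pair table.

    Columns: read_id, chrom1, pos1, len1, strand1, nm1, chrom2, pos2,
    len2, strand2, nm2, status in {mapped, ambiguous, unmapped}. Ambiguous
    and unmapped pairs are excluded from all downstream counting.
    """
    mapper = mapper or ReadMapper(genome)
    rows = []
    for (rid1, s1), (rid2, s2) in zip(reads1, reads2):
        if rid1 != rid2:
            raise ValueError(f"read files out of sync: {rid1} vs {rid2}")
        c1, p1, st1, nm1 = mapper.map_read(s1)
        c2, p2, st2, nm2 = mapper.map_read(s2)
        if c1 is None or c2 is None:
            status = UNMAPPED
        elif c1 == "*" or c2 == "*":
            status = AMBIGUOUS
        else:
            status = "mapped"
        rows.append(
            (rid1, c1 or ".", p1, len(s1), st1, nm1, c2 or ".", p2, len(s2), st2, nm2, status)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "chrom1", "pos1", "len1", "strand1", "nm1",
            "chrom2", "pos2", "len2", "strand2", "nm2",
            "status",
        ],
    )


def deduplicate(pairs: pd.DataFrame) -> pd.DataFrame:
    """Flag PCR duplicates: pairs with identical start positions for both
    ends (end order ignored). One pair per group is retained; the rest get
    label 'duplicate'. Returns a copy with a ``label`` column seeded."""
    df = pairs.copy()
    df["label"] = ""
    mapped = df["status"] == "mapped"
    e1 = list(zip(df["chrom1"], df["pos1"], df["strand1"]))
    e2 = list(zip(df["chrom2"], df["pos2"], df["strand2"]))
    keys = [tuple(sorted([a, b])) if m else None for a, b, m in zip(e1, e2, mapped)]
    df["_dupkey"] = pd.Series(keys, index=df.index, dtype=object)
    dup = df["_dupkey"].notna() & df.duplicated("_dupkey", keep="first")
    df.loc[dup, "label"] = DUPLICATE
    df.loc[df["status"] == AMBIGUOUS, "label"] = AMBIGUOUS
    df.loc[df["status"] == UNMAPPED, "label"] = UNMAPPED
    return df.drop(columns="_dupkey")


def classify(
    pairs: pd.DataFrame,
    window: LibraryWindow,
    genome: GenomeModel,
) -> pd.DataFrame:
    """Label each retained pair consistent or inconsistent.

    Adds ``span`` (circular arc, forward-read start to reverse-read end;
    NaN when undefined) and fills ``label``. Every non-duplicate,
    unambiguous mapped pair ends up exactly one of consistent or
    inconsistent.
    """
    df = pairs.copy()
    if "label" not in df.columns:
        df = deduplicate(df)
    lens = genome.chrom_lengths()
    todo = ((df["status"] == "mapped") & (df["label"] == "")).to_numpy()
    labels = df["label"].to_numpy(dtype=object)

    c1 = df["chrom1"].to_numpy()
    c2 = df["chrom2"].to_numpy()
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    p1 = df["pos1"].to_numpy()
    p2 = df["pos2"].to_numpy()
    l1 = df["len1"].to_numpy()
    l2 = df["len2"].to_numpy()

    chrom_len = np.array([lens.get(c, 1) for c in c1], dtype=np.int64)
    proper = todo & (c1 == c2) & (s1 != s2)
    fwd1 = s1 == "+"
    f_start = np.where(fwd1, p1, p2)
    r_end = np.where(fwd1, p2 + l2, p1 + l1)
    span = np.where(proper, (r_end - f_start) % chrom_len, np.nan)
    in_window = proper & (span >= window.min_bp) & (span <= window.max_bp)

    labels[todo] = INCONSISTENT
    labels[in_window] = CONSISTENT
    df["span"] = span
    df["label"] = labels
    return df


@dataclass
class PairSummary:
    total: int
    consistent: int
    inconsistent: int
    duplicates: int
    ambiguous: int
    unmapped: int


def summarize(pairs: pd.DataFrame) -> PairSummary:
    c = pairs["label"].value_counts()
    return PairSummary(
        total=len(pairs),
        consistent=int(c.get(CONSISTENT, 0)),
        inconsistent=int(c.get(INCONSISTENT, 0)),
        duplicates=int(c.get(DUPLICATE, 0)),
        ambiguous=int(c.get(AMBIGUOUS, 0)),
        unmapped=int(c.get(UNMAPPED, 0)),
    )
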