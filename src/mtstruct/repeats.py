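"""Dispersed-repeat detection by genome self-comparison.

Two detectors share one catalog format:

* :func:`find_exact_repeats` reports all *maximal* exact repeat pairs
  (extendable in neither direction) of at least ``min_len`` bp, on both
  strands, within and between chromosomes, honouring circularity.
* :func:`find_repeat_pairs` is a seed-and-extend local aligner
  (match +1, mismatch -2, gap open -5, gap extend -2, word size 11 by
  default) reporting every hit with raw score >= 30. Under these defaults
  the shortest reportable perfect repeat is exactly 30 bp.

Downstream statistics: union coverage of the genome by repeats (with the
large/small split at 1 kb), the cumulative coverage-by-depth curve whose
y-intercept is the single-copy fraction, and per-pair length/identity
distributions. All statistics are over repeat *pairs*, not copies: a
four-copy family contributes C(4,2) = 6 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import Align

from ._seq import circ_slice, revcomp
from .model import GenomeModel, RepeatCatalog, RepeatCopy, RepeatPair


@dataclass(frozen=True)
class Scoring:
    """Self-comparison scoring; gap of length g costs gap_open + g*gap_extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11


DEFAULT_SCORING = Scoring()
DEFAULT_MIN_SCORE = 30


def _canonical(copy1: RepeatCopy, copy2: RepeatCopy) -> tuple[RepeatCopy, RepeatCopy]:
    a = (copy1.chrom, copy1.start, copy1.end)
    b = (copy2.chrom, copy2.start, copy2.end)
    if a <= b:
        return copy1, copy2
    return copy2, copy1


def _kmer_index(
    seqs: dict[str, str], k: int, circular: dict[str, bool] | None = None
) -> dict[str, list[tuple[str, int]]]:
    """k-mer index; circular chromosomes contribute origin-wrapping k-mers."""
    index: dict[str, list[tuple[str, int]]] = {}
    for cid, s in seqs.items():
        if len(s) < k:
            continue
        circ = True if circular is None else circular[cid]
        d = s + s[: k - 1] if circ else s
        for p in range(len(d) - k + 1):
            index.setdefault(d[p : p + k], []).append((cid, p))
    return index


def _has_left(s: str, p: int, circ: bool) -> bool:
    return circ or p > 0


def _left_char(s: str, p: int) -> str:
    return s[(p - 1) % len(s)]


def _extend_maximal(
    s1: str, p1: int, c1: bool, s2: str, p2: int, c2: bool, k: int
) -> tuple[int, int, int]:
    """Maximally extend an exact k-match; returns (start1, start2, length).

    Circular sequences extend with modular indexing (capped at the shorter
    sequence length so periodic circles cannot loop); linear sequences
    stop at their boundaries.
    """
    n1, n2 = len(s1), len(s2)
    cap = min(n1, n2)
    length = k

    def right_ok(ln: int) -> bool:
        i1, i2 = p1 + ln, p2 + ln
        if not c1 and i1 >= n1:
            return False
        if not c2 and i2 >= n2:
            return False
        return s1[i1 % n1] == s2[i2 % n2]

    while length < cap and right_ok(length):
        length += 1
    off = 0

    def left_ok(o: int) -> bool:
        i1, i2 = p1 - o - 1, p2 - o - 1
        if not c1 and i1 < 0:
            return False
        if not c2 and i2 < 0:
            return False
        return s1[i1 % n1] == s2[i2 % n2]

    while length < cap and left_ok(off):
        off += 1
        length += 1
    return (p1 - off) % n1, (p2 - off) % n2, length


def find_exact_repeats(genome: GenomeModel, min_len: int = 30) -> RepeatCatalog:
    """All maximal perfect repeat pairs of length >= min_len, both strands.

    Boundaries are precise: a reported pair cannot be extended by one base
    in either direction. Tandem-like, partially self-overlapping matches
    are retained; only the trivial identical-interval self-hit is excluded.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    fwd = {cid: c.seq for cid, c in genome.chromosomes.items()}
    circ = {cid: c.circular for cid, c in genome.chromosomes.items()}
    order = {cid: i for i, cid in enumerate(fwd)}
    found: set[tuple] = set()

    index = _kmer_index(fwd, min_len, circ)
    for hits in index.values():
        for i in range(len(hits)):
            for j in range(i, len(hits)):
                (c1, p1), (c2, p2) = hits[i], hits[j]
                if c1 == c2 and p1 == p2:
                    continue
                s1, s2 = fwd[c1], fwd[c2]
                # left-maximality: an earlier seed on this diagonal yields
                # the same maximal match (circles have no left boundary, so
                # a fully periodic whole-circle match is not reported)
                if (
                    _has_left(s1, p1, circ[c1])
                    and _has_left(s2, p2, circ[c2])
                    and _left_char(s1, p1) == _left_char(s2, p2)
                ):
                    continue
                a1, a2, ln = _extend_maximal(
                    s1, p1, circ[c1], s2, p2, circ[c2], min_len
                )
                if c1 == c2 and a1 == a2:
                    continue
                e1 = (a1 + ln) % len(s1) or len(s1)
                e2 = (a2 + ln) % len(s2) or len(s2)
                cp1 = RepeatCopy(c1, a1, e1, "+")
                cp2 = RepeatCopy(c2, a2, e2, "+")
                ca, cb = _canonical(cp1, cp2)
                found.add((ca, cb, ln))

    # Inverted pairs: forward sequence of one chromosome against the
    # reverse complement of another (or itself).
    rc = {cid: revcomp(s) for cid, s in fwd.items()}
    rc_index = _kmer_index(rc, min_len, circ)
    for kmer, hits in index.items():
        rhits = rc_index.get(kmer)
        if not rhits:
            continue
        for c1, p1 in hits:
            for c2, p2 in rhits:
                if order[c2] < order[c1]:
                    continue  # mirror enumeration handles the other order
                s1, s2 = fwd[c1], rc[c2]
                if (
                    _has_left(s1, p1, circ[c1])
                    and _has_left(s2, p2, circ[c2])
                    and _left_char(s1, p1) == _left_char(s2, p2)
                ):
                    continue
                a1, a2, ln = _extend_maximal(
                    s1, p1, circ[c1], s2, p2, circ[c2], min_len
                )
                n2 = len(s2)
                # map the RC interval back onto forward coordinates
                b_start = (n2 - (a2 + ln)) % n2
                b_end = (n2 - a2) % n2 or n2
                cp1 = RepeatCopy(c1, a1, (a1 + ln) % len(s1) or len(s1), "+")
                cp2 = RepeatCopy(c2, b_start, b_end, "-")
                if (cp1.chrom, cp1.start, cp1.end) == (cp2.chrom, cp2.start, cp2.end):
                    continue  # perfect palindrome over the same interval
                ca, cb = _canonical(cp1, cp2)
                if ca is not cp1:
                    ca = RepeatCopy(ca.chrom, ca.start, ca.end, "+")
                    cb = RepeatCopy(cb.chrom, cb.start, cb.end, "-")
                found.add((ca, cb, ln))

    pairs = [
        RepeatPair(ca, cb, ln, 100.0, ln)
        for ca, cb, ln in sorted(found, key=lambda t: (t[0], t[1], t[2]))
    ]
    return RepeatCatalog(pairs, {"detector": "exact", "min_len": min_len})


# ---------------------------------------------------------------------------
# Imperfect repeats: seed-and-extend local alignment
# ---------------------------------------------------------------------------

def _aligner(sc: Scoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = sc.match
    al.mismatch_score = sc.mismatch
    # first gap position costs open+extend, each further one costs extend
    al.open_gap_score = -(sc.gap_open + sc.gap_extend)
    al.extend_gap_score = -sc.gap_extend
    return al


def _cluster_seeds(
    seeds: list[tuple[int, int]], diag_tol: int = 32, gap: int = 120
) -> list[tuple[int, int, int, int]]:
    """Cluster (p1, p2) seed matches into candidate regions.

    Seeds are grouped by approximate diagonal and chained along p1; returns
    (p1_lo, p1_hi, p2_lo, p2_hi) per cluster (k-mer start coordinates).
    """
    seeds = sorted(seeds, key=lambda t: ((t[1] - t[0]) // diag_tol, t[0]))
    clusters = []
    cur: list[tuple[int, int]] = []
    cur_band = None
    last_p1 = None
    for p1, p2 in seeds:
        band = (p2 - p1) // diag_tol
        if cur and (band != cur_band or p1 - last_p1 > gap):
            clusters.append(cur)
            cur = []
        cur_band = band
        cur.append((p1, p2))
        last_p1 = p1
    if cur:
        clusters.append(cur)
    out = []
    for cl in clusters:
        p1s = [p for p, _ in cl]
        p2s = [q for _, q in cl]
        out.append((min(p1s), max(p1s), min(p2s), max(p2s)))
    return out


def _alignment_stats(aln) -> tuple[int, int, float]:
    """(aligned_columns, score-independent identity%, ...) from an alignment."""
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    ident = 100.0 * counts.identities / columns if columns else 0.0
    return columns, counts.identities, ident


def find_repeat_pairs(
    genome: GenomeModel,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: int = DEFAULT_MIN_SCORE,
    max_align_window: int = 12_000,
) -> RepeatCatalog:
    """Seed-and-extend self-comparison; hits with raw score >= min_score.

    Overlapping hits are reported as distinct pairs (no chaining or
    merging); a hit is excluded only when the two intervals are identical.
    Candidate regions wider than ``max_align_window`` are skipped (very
    large perfect repeats are still reported by
    :func:`find_exact_repeats`, which has no such bound).
    """
    k = scoring.word_size
    fwd = {cid: c.seq for cid, c in genome.chromosomes.items()}
    circ = {cid: c.circular for cid, c in genome.chromosomes.items()}
    if all(len(s) < k for s in fwd.values()):
        return RepeatCatalog([], {"detector": "seed-extend", "empty": True})
    order = {cid: i for i, cid in enumerate(fwd)}
    rc = {cid: revcomp(s) for cid, s in fwd.items()}
    aligner = _aligner(scoring)

    # collect seed pairs keyed by (chrom1, chrom2, strand)
    groups: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    fwd_index = _kmer_index(fwd, k, circ)
    for hits in fwd_index.values():
        for i in range(len(hits)):
            for j in range(i, len(hits)):
                (c1, p1), (c2, p2) = hits[i], hits[j]
                if c1 == c2 and p1 == p2:
                    continue
                if (order[c1], p1) > (order[c2], p2):
                    (c1, p1), (c2, p2) = (c2, p2), (c1, p1)
                groups.setdefault((c1, c2, "+"), []).append((p1, p2))
    rc_index = _kmer_index(rc, k, circ)
    for kmer, hits in fwd_index.items():
        rhits = rc_index.get(kmer)
        if not rhits:
            continue
        for c1, p1 in hits:
            for c2, p2 in rhits:
                if order[c2] < order[c1]:
                    continue
                groups.setdefault((c1, c2, "-"), []).append((p1, p2))

    found: dict[tuple, RepeatPair] = {}
    for (c1, c2, strand), seeds in groups.items():
        s1 = fwd[c1]
        s2 = fwd[c2] if strand == "+" else rc[c2]
        n1, n2 = len(s1), len(s2)
        for q_lo, q_hi, s_lo, s_hi in _cluster_seeds(seeds):
            if q_hi - q_lo > max_align_window or s_hi - s_lo > max_align_window:
                continue
            margin = 30 + (q_hi - q_lo) // 8
            w1_lo, w1_hi = q_lo - margin, q_hi + k + margin
            w2_lo, w2_hi = s_lo - margin, s_hi + k + margin
            # clamp windows to one genome length; linear chromosomes also
            # clamp at their boundaries
            w1_hi = min(w1_hi, w1_lo + n1)
            w2_hi = min(w2_hi, w2_lo + n2)
            if not circ[c1]:
                w1_lo, w1_hi = max(0, w1_lo), min(n1, w1_hi)
            if not circ[c2]:
                w2_lo, w2_hi = max(0, w2_lo), min(n2, w2_hi)
            win1 = circ_slice(s1, w1_lo % n1, w1_hi % n1) if w1_hi - w1_lo < n1 else s1[w1_lo % n1:] + s1[: w1_lo % n1]
            win2 = circ_slice(s2, w2_lo % n2, w2_hi % n2) if w2_hi - w2_lo < n2 else s2[w2_lo % n2:] + s2[: w2_lo % n2]
            try:
                alns = aligner.align(win1, win2)
                best = alns[0]
            except (IndexError, OverflowError):
                continue
            if best.score < min_score:
                continue
            (q_start, q_end) = best.aligned[0][0][0], best.aligned[0][-1][1]
            (t_start, t_end) = best.aligned[1][0][0], best.aligned[1][-1][1]
            a_start = (w1_lo + q_start) % n1
            a_end = (w1_lo + q_end) % n1
            if strand == "+":
                b_start = (w2_lo + t_start) % n2
                b_end = (w2_lo + t_end) % n2
            else:
                b_start = (n2 - (w2_lo + t_end)) % n2
                b_end = (n2 - (w2_lo + t_start)) % n2
            columns, _idents, ident = _alignment_stats(best)
            cp1 = RepeatCopy(c1, int(a_start), int(a_end), "+")
            cp2 = RepeatCopy(c2, int(b_start), int(b_end), "-" if strand == "-" else "+")
            if (cp1.chrom, cp1.start, cp1.end) == (cp2.chrom, cp2.start, cp2.end):
                continue
            ca, cb = _canonical(cp1, cp2)
            if strand == "-" and ca.strand == "-":
                ca = RepeatCopy(ca.chrom, ca.start, ca.end, "+")
                cb = RepeatCopy(cb.chrom, cb.start, cb.end, "-")
            key = (ca, cb)
            pair = RepeatPair(ca, cb, columns, ident, int(best.score))
            prev = found.get(key)
            if prev is None or pair.raw_score > prev.raw_score:
                found[key] = pair

    pairs = sorted(found.values(), key=lambda p: (p.copy_a, p.copy_b))
    return RepeatCatalog(
        pairs,
        {
            "detector": "seed-extend",
            "scoring": scoring,
            "min_score": min_score,
        },
    )


# ---------------------------------------------------------------------------
# Landscape statistics
# ---------------------------------------------------------------------------

def _copy_mask_indices(copy: RepeatCopy, n: int) -> np.ndarray:
    if copy.end > copy.start:
        return np.arange(copy.start, copy.end)
    return np.concatenate([np.arange(copy.start, n), np.arange(0, copy.end)])


@dataclass
class CoverageResult:
    fraction: float
    large_fraction: float  # pairs > 1 kb
    small_fraction: float  # pairs <= 1 kb
    masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def intervals(self) -> list[tuple[str, int, int]]:
        """Masked regions as (chrom, start, end) runs (BED-ready)."""
        out = []
        for cid, mask in self.masks.items():
            padded = np.concatenate([[False], mask, [False]])
            diff = np.diff(padded.astype(np.int8))
            starts = np.nonzero(diff == 1)[0]
            ends = np.nonzero(diff == -1)[0]
            out.extend((cid, int(s), int(e)) for s, e in zip(starts, ends))
        return out


LARGE_REPEAT_BP = 1_000


def repeat_coverage(
    genome: GenomeModel,
    catalog: RepeatCatalog,
    min_len: int = 0,
    min_identity: float = 0.0,
) -> CoverageResult:
    """Fraction of the genome lying in >= 1 qualifying repeat interval.

    Also reports the split into large (> 1 kb) and small (<= 1 kb) pairs.
    """
    lens = genome.chrom_lengths()
    total = sum(lens.values())
    masks = {cid: np.zeros(n, dtype=bool) for cid, n in lens.items()}
    large = {cid: np.zeros(n, dtype=bool) for cid, n in lens.items()}
    small = {cid: np.zeros(n, dtype=bool) for cid, n in lens.items()}
    for pair in catalog:
        if pair.aligned_length < min_len or pair.identity < min_identity:
            continue
        bucket = large if pair.aligned_length > LARGE_REPEAT_BP else small
        for copy in (pair.copy_a, pair.copy_b):
            idx = _copy_mask_indices(copy, lens[copy.chrom])
            masks[copy.chrom][idx] = True
            bucket[copy.chrom][idx] = True
    frac = sum(int(m.sum()) for m in masks.values()) / total if total else 0.0
    lfrac = sum(int(m.sum()) for m in large.values()) / total if total else 0.0
    sfrac = sum(int(m.sum()) for m in small.values()) / total if total else 0.0
    return CoverageResult(frac, lfrac, sfrac, masks)


def repeat_depth_curve(genome: GenomeModel, catalog: RepeatCatalog) -> pd.DataFrame:
    """Cumulative genome fraction vs repeat-match depth.

    Row d gives the fraction of positions matching <= d-1 other loci (the
    per-position count of catalog intervals covering it); the d=1 value is
    the single-copy fraction of the genome, and the curve reaches 1.0 at
    the maximum depth.
    """
    lens = genome.chrom_lengths()
    counts = {cid: np.zeros(n, dtype=np.int32) for cid, n in lens.items()}
    for pair in catalog:
        for copy in (pair.copy_a, pair.copy_b):
            idx = _copy_mask_indices(copy, lens[copy.chrom])
            counts[copy.chrom][idx] += 1
    allc = (
        np.concatenate(list(counts.values()))
        if counts
        else np.zeros(0, dtype=np.int32)
    )
    total = len(allc)
    max_d = int(allc.max()) + 1 if total else 1
    depths = np.arange(1, max_d + 1)
    frac = np.array([(allc <= d - 1).sum() / total for d in depths]) if total else np.ones(1)
    return pd.DataFrame({"depth": depths, "cumulative_fraction": frac})


def per_base_match_counts(genome: GenomeModel, catalog: RepeatCatalog) -> dict[str, np.ndarray]:
    """Per-position count of catalog intervals covering the position."""
    lens = genome.chrom_lengths()
    counts = {cid: np.zeros(n, dtype=np.int32) for cid, n in lens.items()}
    for pair in catalog:
        for copy in (pair.copy_a, pair.copy_b):
            idx = _copy_mask_indices(copy, lens[copy.chrom])
            counts[copy.chrom][idx] += 1
    return counts


def pair_statistics(
    catalog: RepeatCatalog,
    min_len_for_identity: int = 300,
    length_bins: Optional[Iterable[int]] = None,
) -> dict:
    """Length histogram (by pair count and summed pair length) and the
    identity distribution restricted to pairs > min_len_for_identity bp."""
    lengths = np.array([p.aligned_length for p in catalog], dtype=np.int64)
    idents = np.array(
        [p.identity for p in catalog if p.aligned_length > min_len_for_identity]
    )
    if length_bins is None:
        length_bins = [0, 50, 100, 300, 1_000, 3_000, 10_000, 100_000, 10_000_000]
    bins = np.asarray(list(length_bins))
    which = np.digitize(lengths, bins) - 1 if len(lengths) else np.zeros(0, int)
    rows = []
    for b in range(len(bins) - 1):
        sel = which == b
        rows.append(
            (
                f"{bins[b]}-{bins[b + 1]}",
                int(sel.sum()),
                int(lengths[sel].sum()),
            )
        )
    hist = pd.DataFrame(rows, columns=["length_bin", "n_pairs", "summed_bp"])
    return {
        "length_histogram": hist,
        "identities": idents,
        "n_pairs": int(len(lengths)),
        "total_pair_length": int(lengths.sum()) if len(lengths) else 0,
    }
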