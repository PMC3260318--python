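"""Quantification of repeat-mediated recombinant genome conformations.

Because of recombination, a two-copy repeat can occupy four junction
environments: the two reference environments (each copy between its own
flanks) and the two recombinant environments obtained by exchanging the
flanks of the copies. Deduplicated, unambiguous read pairs vote for the
environments they span:

* C1 / C2 — consistent pairs whose ends flank copy A / copy B;
* R1 / R2 — inconsistent pairs whose ends, after the flank exchange,
  would flank a copy at a window-compatible span and proper orientation.

The recombinant-conformation frequency for the pair is
(R1 + R2) / (C1 + C2 + R1 + R2).

Eligibility filters, the reversed-orientation control (re-running the
assay with one copy's orientation flipped, which detects only
inverted-orientation products and therefore measures the chimera/artifact
floor), chromosome-autonomy calls, repeat-masked depth evenness, and
collapsed-tandem diagnostics all live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import gc_content
from .model import (
    CONSISTENT,
    INCONSISTENT,
    AutonomyReport,
    GenomeModel,
    LibraryWindow,
    RepeatCatalog,
    RepeatCopy,
    RepeatPair,
)

MIN_ASSAY_LEN = 50
MIN_ASSAY_IDENTITY = 95.0
DEFAULT_MIN_SUPPORT = 5


class AssayUndefinedError(ValueError):
    """The repeat cannot be assayed (e.g. longer than the library span)."""


# ---------------------------------------------------------------------------
# Junction environments and support counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Region:
    """A w-bp flank region read in a fixed orientation.

    ``orient`` '+': env coordinate increases with reference coordinate,
    region = [ref_start, ref_start + w). '-': the region is read
    reverse-complemented, env coordinate runs from ref_start + w down to
    ref_start.
    """

    chrom: str
    ref_start: int
    orient: str


def _upstream(copy: RepeatCopy, w: int, L: int) -> _Region:
    if copy.strand == "+":
        return _Region(copy.chrom, (copy.start - w) % L, "+")
    return _Region(copy.chrom, copy.end % L, "-")


def _downstream(copy: RepeatCopy, w: int, L: int) -> _Region:
    if copy.strand == "+":
        return _Region(copy.chrom, copy.end % L, "+")
    return _Region(copy.chrom, (copy.start - w) % L, "-")


def junction_environments(
    pair: RepeatPair, genome: GenomeModel, w: int
) -> dict[str, tuple[_Region, _Region]]:
    """The four flank-repeat-flank environments of a repeat pair.

    Each environment is (upstream region, downstream region) around a
    virtual copy; the recombinant environments pair the upstream flank of
    one copy with the downstream flank of the other, which is exactly the
    junction structure produced by crossover between the copies.
    """
    lens = genome.chrom_lengths()
    a, b = pair.copy_a, pair.copy_b
    la, lb = lens[a.chrom], lens[b.chrom]
    return {
        "ref1": (_upstream(a, w, la), _downstream(a, w, la)),
        "ref2": (_upstream(b, w, lb), _downstream(b, w, lb)),
        "rec1": (_upstream(b, w, lb), _downstream(a, w, la)),
        "rec2": (_upstream(a, w, la), _downstream(b, w, lb)),
    }


def _env_transform(
    region: _Region,
    w: int,
    chrom: np.ndarray,
    pos: np.ndarray,
    rlen: np.ndarray,
    strand: np.ndarray,
    lens: dict[str, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized read -> environment-coordinate transform.

    Returns (inside, env_pos, env_fwd): ``inside`` marks reads lying fully
    within the region; ``env_pos`` is the read start in environment
    coordinates (offset 0 at the region's upstream edge); ``env_fwd`` is
    True when the read points forward in environment orientation.
    """
    L = lens[region.chrom]
    on = chrom == region.chrom
    off = (pos - region.ref_start) % L
    inside = on & (off + rlen <= w)
    if region.orient == "+":
        env_pos = off
        env_fwd = strand == "+"
    else:
        env_pos = w - off - rlen
        env_fwd = strand == "-"
    return inside, env_pos, env_fwd


@dataclass
class SupportCounts:
    c1: int
    c2: int
    r1: int
    r2: int

    @property
    def total(self) -> int:
        return self.c1 + self.c2 + self.r1 + self.r2

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.c1, self.c2, self.r1, self.r2)


def count_conformation_support(
    pair: RepeatPair,
    labelled_pairs: pd.DataFrame,
    window: LibraryWindow,
    genome: GenomeModel,
) -> SupportCounts:
    """Count deduplicated read pairs supporting each junction environment.

    Pairs with either end overlapping the repeat interval are never
    counted (a read must sit fully inside a flank). Consistent pairs feed
    the reference counts, inconsistent pairs the recombinant counts.
    """
    lens = genome.chrom_lengths()
    r_len = (
        pair.copy_a.length(lens[pair.copy_a.chrom])
        + pair.copy_b.length(lens[pair.copy_b.chrom])
    ) // 2
    if r_len >= window.max_bp:
        raise AssayUndefinedError(
            f"repeat of {r_len} bp exceeds the {window.max_bp}-bp library span"
        )
    w = window.max_bp
    envs = junction_environments(pair, genome, w)

    df = labelled_pairs
    usable = df["label"].isin([CONSISTENT, INCONSISTENT]).to_numpy()
    lab = df["label"].to_numpy()
    c1 = df["chrom1"].to_numpy()
    c2 = df["chrom2"].to_numpy()
    p1 = df["pos1"].to_numpy()
    p2 = df["pos2"].to_numpy()
    l1 = df["len1"].to_numpy()
    l2 = df["len2"].to_numpy()
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()

    counts = {}
    for name, (up, down) in envs.items():
        want = CONSISTENT if name.startswith("ref") else INCONSISTENT
        ok_label = usable & (lab == want)
        n = 0
        # either end may be the upstream one
        for (ca, pa, la, sa), (cb, pb, lb_, sb) in (
            ((c1, p1, l1, s1), (c2, p2, l2, s2)),
            ((c2, p2, l2, s2), (c1, p1, l1, s1)),
        ):
            in_up, up_pos, up_fwd = _env_transform(up, w, ca, pa, la, sa, lens)
            in_dn, dn_pos, dn_fwd = _env_transform(down, w, cb, pb, lb_, sb, lens)
            span = (w + r_len + dn_pos + lb_) - up_pos
            hit = (
                ok_label
                & in_up
                & in_dn
                & up_fwd
                & ~dn_fwd
                & (span >= window.min_bp)
                & (span <= window.max_bp)
            )
            n += int(hit.sum())
        counts[name] = n
    return SupportCounts(counts["ref1"], counts["ref2"], counts["rec1"], counts["rec2"])


def recombinant_frequency(counts: SupportCounts | tuple) -> Optional[float]:
    """(R1+R2) / (C1+C2+R1+R2); None (undefined) when all counts are zero."""
    if isinstance(counts, tuple):
        counts = SupportCounts(*counts)
    if counts.total == 0:
        return None
    return (counts.r1 + counts.r2) / counts.total


def frequency_percent(freq: float) -> int:
    """Percent display, rounded half-up to the nearest integer."""
    import math

    return int(math.floor(freq * 100 + 0.5))


def reversed_control(
    pair: RepeatPair,
    labelled_pairs: pd.DataFrame,
    window: LibraryWindow,
    genome: GenomeModel,
) -> SupportCounts:
    """Re-run the assay with one copy's orientation reversed.

    Detects only recombination between the copies aligned in *opposite*
    orientations, so on genuine direct-repeat recombination it measures
    the chimera/artifact floor.
    """
    b = pair.copy_b
    flipped = RepeatPair(
        pair.copy_a,
        RepeatCopy(b.chrom, b.start, b.end, "-" if b.strand == "+" else "+"),
        pair.aligned_length,
        pair.identity,
        pair.raw_score,
    )
    return count_conformation_support(flipped, labelled_pairs, window, genome)


# ---------------------------------------------------------------------------
# Eligibility filtering
# ---------------------------------------------------------------------------

def _interval_distance(c1: RepeatCopy, c2: RepeatCopy, lens: dict[str, int]) -> float:
    """Circular distance between two intervals; 0 if they overlap, inf if on
    different chromosomes."""
    if c1.chrom != c2.chrom:
        return float("inf")
    L = lens[c1.chrom]
    len1, len2 = c1.length(L), c2.length(L)
    gap1 = (c2.start - c1.end) % L
    gap2 = (c1.start - c2.end) % L
    if gap1 + gap2 == L - len1 - len2:
        return min(gap1, gap2)
    return 0.0


def _point_distance(copy: RepeatCopy, point: int, L: int) -> int:
    """Circular distance from an interval to a point (0 if inside)."""
    off = (point - copy.start) % L
    if off < copy.length(L):
        return 0
    d1 = (point - copy.end) % L
    d2 = (copy.start - point) % L
    return min(d1, d2)


@dataclass
class EligibilityOptions:
    min_len: int = MIN_ASSAY_LEN
    min_identity: float = MIN_ASSAY_IDENTITY
    correlated_rule: bool = True
    adjacency_rule: bool = False  # short-span-library rule (100 bp / >500 bp)
    subsample_short: Optional[tuple[float, int, int]] = None  # (frac, len, seed)


def filter_assayable(
    catalog: RepeatCatalog,
    window: LibraryWindow,
    genome: GenomeModel,
    options: EligibilityOptions | None = None,
) -> pd.DataFrame:
    """Annotate every catalog pair with assay eligibility and a reason.

    Exclusion rules, applied in order: minimum length 50 bp and identity
    95%; copies separated by less than the maximum library span; a
    correlated pair of larger repeats within the maximum span of each
    focal copy (interpretation exposed as ``correlated_rule``); for
    short-span libraries, a copy within 100 bp of the start of any other
    repeat > 500 bp (``adjacency_rule``); optional seeded retention of a
    random fraction of short pairs. The minimum-support rule (five
    consistent pairs spanning each copy) applies after counting, in
    :func:`assay_repeat`.
    """
    opts = options or EligibilityOptions()
    lens = genome.chrom_lengths()
    pairs = list(catalog)
    rows = []
    rng = None
    if opts.subsample_short is not None:
        frac, cutoff, seed = opts.subsample_short
        rng = np.random.default_rng(seed)
        keep_short = {
            i
            for i, p in enumerate(pairs)
            if p.aligned_length >= cutoff or rng.random() < frac
        }
    for i, p in enumerate(pairs):
        reason = ""
        if p.aligned_length < opts.min_len:
            reason = "min_length"
        elif p.identity < opts.min_identity:
            reason = "min_identity"
        elif (
            not p.cross_chromosome
            and _interval_distance(p.copy_a, p.copy_b, lens) < window.max_bp
        ):
            reason = "separation"
        if not reason and opts.correlated_rule:
            for q in pairs:
                if q is p or q.aligned_length <= p.aligned_length:
                    continue
                qa, qb = q.copy_a, q.copy_b
                near_a = min(
                    _interval_distance(qa, p.copy_a, lens),
                    _interval_distance(qb, p.copy_a, lens),
                )
                near_b = min(
                    _interval_distance(qa, p.copy_b, lens),
                    _interval_distance(qb, p.copy_b, lens),
                )
                if near_a <= window.max_bp and near_b <= window.max_bp:
                    reason = "correlated_larger_pair"
                    break
        if not reason and opts.adjacency_rule:
            for q in pairs:
                if q is p or q.aligned_length <= 500:
                    continue
                for qc in (q.copy_a, q.copy_b):
                    L = lens[qc.chrom]
                    for pc in (p.copy_a, p.copy_b):
                        if pc.chrom == qc.chrom and _point_distance(pc, qc.start, L) <= 100:
                            reason = "adjacent_large_repeat"
                            break
                    if reason:
                        break
                if reason:
                    break
        if not reason and opts.subsample_short is not None and i not in keep_short:
            reason = "subsampled_out"
        rows.append(
            (
                i,
                p.copy_a.chrom,
                p.copy_a.start,
                p.copy_b.chrom,
                p.copy_b.start,
                p.aligned_length,
                p.identity,
                reason == "",
                reason,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_idx",
            "chromA", "startA", "chromB", "startB",
            "length", "identity", "eligible", "reason",
        ],
    )


@dataclass
class RecombAssay:
    """Per-repeat assay outcome."""

    pair: RepeatPair
    eligible: bool
    exclusion_reason: str = ""
    counts: Optional[SupportCounts] = None
    frequency: Optional[float] = None
    control_counts: Optional[SupportCounts] = None
    control_frequency: Optional[float] = None


def assay_repeat(
    pair: RepeatPair,
    labelled_pairs: pd.DataFrame,
    window: LibraryWindow,
    genome: GenomeModel,
    min_support: int = DEFAULT_MIN_SUPPORT,
    control: bool = False,
) -> RecombAssay:
    """Count support and compute the recombinant frequency for one pair.

    The frequency is reported only when at least ``min_support``
    consistent read pairs span *each* copy (C1 and C2 separately).
    """
    try:
        counts = count_conformation_support(pair, labelled_pairs, window, genome)
    except AssayUndefinedError as e:
        return RecombAssay(pair, False, str(e))
    assay = RecombAssay(pair, True, counts=counts)
    if counts.c1 < min_support or counts.c2 < min_support:
        assay.exclusion_reason = "min_support"
        assay.eligible = False
    else:
        assay.frequency = recombinant_frequency(counts)
    if control:
        assay.control_counts = reversed_control(pair, labelled_pairs, window, genome)
        assay.control_frequency = recombinant_frequency(assay.control_counts)
    return assay


def run_assays(
    catalog: RepeatCatalog,
    labelled_pairs: pd.DataFrame,
    window: LibraryWindow,
    genome: GenomeModel,
    options: EligibilityOptions | None = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
    control: bool = False,
) -> list[RecombAssay]:
    """Filter the catalog and assay every eligible pair."""
    elig = filter_assayable(catalog, window, genome, options)
    out = []
    for i, pair in enumerate(catalog):
        row = elig.iloc[i]
        if not row["eligible"]:
            out.append(RecombAssay(pair, False, row["reason"]))
            continue
        out.append(
            assay_repeat(pair, labelled_pairs, window, genome, min_support, control)
        )
    return out


def assays_to_frame(assays: Sequence[RecombAssay]) -> pd.DataFrame:
    rows = []
    for a in assays:
        c = a.counts.as_tuple() if a.counts else (0, 0, 0, 0)
        rows.append(
            (
                a.pair.copy_a.chrom, a.pair.copy_a.start, a.pair.copy_a.end,
                a.pair.copy_b.chrom, a.pair.copy_b.start, a.pair.copy_b.end,
                a.pair.copy_b.strand,
                a.pair.aligned_length, round(a.pair.identity, 2),
                a.eligible, a.exclusion_reason,
                *c,
                np.nan if a.frequency is None else round(a.frequency, 4),
                np.nan if a.control_frequency is None else round(a.control_frequency, 4),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chromA", "startA", "endA", "chromB", "startB", "endB", "strandB",
            "length", "identity", "eligible", "reason",
            "C1", "C2", "R1", "R2", "frequency", "control_frequency",
        ],
    )


# ---------------------------------------------------------------------------
# Chromosome-level structure reports
# ---------------------------------------------------------------------------

def chromosome_autonomy(
    genome: GenomeModel,
    catalog: RepeatCatalog,
    assays: Sequence[RecombAssay],
    min_shared_len: int = 100,
    support_threshold: float = 0.995,
) -> list[AutonomyReport]:
    """Call each chromosome autonomous or repeat-linked.

    A chromosome is autonomous iff it shares no repeat longer than
    ``min_shared_len`` with any other chromosome AND, for every shorter
    shared repeat, the fraction of read pairs supporting the standalone
    (reference) conformation exceeds ``support_threshold``. Chromosomes
    untouched by the catalog are vacuously autonomous and flagged.
    """
    by_pair = {(a.pair.copy_a, a.pair.copy_b): a for a in assays}
    reports = []
    for cid in genome.chromosomes:
        shared = [
            p
            for p in catalog
            if p.cross_chromosome and cid in (p.copy_a.chrom, p.copy_b.chrom)
        ]
        touched = any(
            cid in (p.copy_a.chrom, p.copy_b.chrom) for p in catalog
        )
        n_large = sum(1 for p in shared if p.aligned_length > min_shared_len)
        freqs = []
        for p in shared:
            if p.aligned_length > min_shared_len:
                continue
            a = by_pair.get((p.copy_a, p.copy_b))
            if a is not None and a.frequency is not None:
                freqs.append(a.frequency)
        max_freq = max(freqs) if freqs else None
        ok_support = all(1.0 - f > support_threshold for f in freqs)
        autonomous = n_large == 0 and ok_support
        reports.append(
            AutonomyReport(cid, n_large, max_freq, autonomous, vacuous=not touched)
        )
    return reports


def _read_depth(
    labelled_pairs: pd.DataFrame, genome: GenomeModel
) -> dict[str, np.ndarray]:
    """Per-base read depth from mapped, non-duplicate read alignments."""
    lens = genome.chrom_lengths()
    depth = {cid: np.zeros(n, dtype=np.int64) for cid, n in lens.items()}
    use = labelled_pairs["label"].isin([CONSISTENT, INCONSISTENT])
    sub = labelled_pairs[use]
    for c_col, p_col, l_col in (("chrom1", "pos1", "len1"), ("chrom2", "pos2", "len2")):
        for cid, grp in sub.groupby(c_col):
            n = lens[cid]
            arr = depth[cid]
            starts = grp[p_col].to_numpy() % n
            rlens = grp[l_col].to_numpy()
            for s, ln in zip(starts, rlens):
                e = s + ln
                if e <= n:
                    arr[s:e] += 1
                else:
                    arr[s:] += 1
                    arr[: e - n] += 1
    return depth


def depth_evenness(
    labelled_pairs: pd.DataFrame,
    genome: GenomeModel,
    repeat_mask: Optional[dict[str, np.ndarray]] = None,
) -> tuple[pd.DataFrame, float]:
    """Repeat-masked per-chromosome mean depth, GC%, and the max/min
    fold ratio of mean depths (fully masked chromosomes are excluded from
    the ratio and flagged)."""
    depth = _read_depth(labelled_pairs, genome)
    rows = []
    means = []
    for cid, chrom in genome.chromosomes.items():
        d = depth[cid]
        if repeat_mask is not None and cid in repeat_mask:
            keep = ~repeat_mask[cid]
        else:
            keep = np.ones(len(d), dtype=bool)
        excluded = not keep.any()
        mean = float(d[keep].mean()) if not excluded else np.nan
        rows.append((cid, len(chrom), mean, round(gc_content(chrom.seq), 2), excluded))
        if not excluded:
            means.append(mean)
    df = pd.DataFrame(
        rows, columns=["chrom", "length", "mean_depth", "gc_percent", "fully_masked"]
    )
    fold = float(max(means) / min(means)) if means and min(means) > 0 else float("nan")
    return df, fold


def collapse_diagnostics(
    labelled_pairs: pd.DataFrame,
    genome: GenomeModel,
    repeat_mask: Optional[dict[str, np.ndarray]] = None,
    window_bp: int = 500,
    depth_fold: float = 2.0,
    min_boundary_inconsistent: int = 3,
    boundary_bp: int = 1_000,
) -> pd.DataFrame:
    """Flag candidate collapsed-tandem misassemblies.

    An interval is flagged when its windowed read depth reaches
    ``depth_fold`` times the chromosome median AND inconsistent read-pair
    ends cluster within ``boundary_bp`` of its boundaries — the joint
    signature distinguishing a collapsed tandem from a genuine autonomous
    subcircle (which shows neither).
    """
    depth = _read_depth(labelled_pairs, genome)
    inc = labelled_pairs[labelled_pairs["label"] == INCONSISTENT]
    rows = []
    for cid, chrom in genome.chromosomes.items():
        d = depth[cid].astype(float)
        n = len(d)
        med = float(np.median(d))
        if med == 0:
            continue
        nwin = max(1, n // window_bp)
        edges = np.linspace(0, n, nwin + 1).astype(int)
        wmeans = np.array(
            [d[a:b].mean() if b > a else 0.0 for a, b in zip(edges[:-1], edges[1:])]
        )
        hot = wmeans >= depth_fold * med
        # merge adjacent hot windows
        i = 0
        while i < nwin:
            if not hot[i]:
                i += 1
                continue
            j = i
            while j + 1 < nwin and hot[j + 1]:
                j += 1
            start, end = int(edges[i]), int(edges[j + 1])
            ends = []
            for c_col, p_col in (("chrom1", "pos1"), ("chrom2", "pos2")):
                sel = inc[inc[c_col] == cid]
                ends.extend(sel[p_col].tolist())
            ends = np.array(ends, dtype=np.int64) if ends else np.zeros(0, np.int64)
            near = (
                (np.abs((ends - start + n // 2) % n - n // 2) <= boundary_bp)
                | (np.abs((ends - end + n // 2) % n - n // 2) <= boundary_bp)
            )
            n_near = int(near.sum())
            if n_near >= min_boundary_inconsistent:
                rows.append(
                    (cid, start, end, float(wmeans[i : j + 1].mean()), med, n_near)
                )
            i = j + 1
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end",
            "mean_depth", "chrom_median_depth", "n_boundary_inconsistent",
        ],
    )
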