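"""Species-unique indel census from multiple sequence alignments.

Events are per-taxon maximal runs of gap columns (outside masked column
ranges such as unalignable gene ends). An event is *unique* to a taxon
when no event from any other taxon overlaps its column interval — a
single shared column disqualifies both. Polarity is assigned against a
designated outgroup: the event is a deletion in the focal taxon when the
outgroup carries sequence across the run, an insertion (in the non-gapped
taxa) when the outgroup is gapped over the whole run, and undetermined
when the outgroup is partially gapped; undetermined events still count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DELETION = "deletion"
INSERTION = "insertion"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class IndelEvent:
    taxon: str
    start: int  # alignment columns, half-open
    end: int
    kind: str
    truncated: bool = False  # gap run clipped at a mask edge

    @property
    def length(self) -> int:
        return self.end - self.start


def _mask_array(n_cols: int, mask_ranges: Sequence[tuple[int, int]]) -> np.ndarray:
    m = np.zeros(n_cols, dtype=bool)
    for s, e in mask_ranges:
        m[max(0, s) : min(n_cols, e)] = True
    return m


def call_indels(
    alignment: dict[str, str],
    mask_ranges: Sequence[tuple[int, int]] = (),
    outgroup: Optional[str] = None,
) -> list[IndelEvent]:
    """Call per-taxon maximal gap-run events from an aligned FASTA dict.

    Rows must have equal length (ragged input fails). Runs overlapping a
    mask are truncated at the mask edge and flagged.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    n_cols = lengths.pop()
    masked = _mask_array(n_cols, mask_ranges)
    out_row = alignment.get(outgroup) if outgroup else None

    events: list[IndelEvent] = []
    for taxon, row in alignment.items():
        gap = np.array([c == "-" for c in row]) & ~masked
        padded = np.concatenate([[False], gap, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for s, e in zip(starts, ends):
            truncated = (s > 0 and masked[s - 1] and row[s - 1] == "-") or (
                e < n_cols and masked[e] and row[e] == "-"
            )
            if out_row is None or taxon == outgroup:
                kind = UNDETERMINED
            else:
                og = out_row[s:e]
                n_gap = og.count("-")
                if n_gap == 0:
                    kind = DELETION
                elif n_gap == len(og):
                    kind = INSERTION
                else:
                    kind = UNDETERMINED
            events.append(IndelEvent(taxon, int(s), int(e), kind, truncated))
    return events


def unique_indels(
    events: Sequence[IndelEvent],
    ingroup_taxa: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-taxon counts and sizes of indels unique to a single taxon.

    An event counts for taxon t iff no event from any *other* taxon
    overlaps its column interval (overlap inclusive of single shared
    columns). Returns one row per unique event; aggregate with
    :func:`census_summary`.
    """
    rows = []
    for ev in events:
        if ingroup_taxa is not None and ev.taxon not in ingroup_taxa:
            continue
        clash = any(
            o.taxon != ev.taxon and o.start < ev.end and ev.start < o.end
            for o in events
        )
        if clash:
            continue
        rows.append((ev.taxon, ev.start, ev.end, ev.length, ev.kind, ev.truncated))
    return pd.DataFrame(
        rows, columns=["taxon", "start", "end", "length", "kind", "truncated"]
    )


def census_summary(
    unique: pd.DataFrame, size_bins: Sequence[int] = (1, 2, 6, 11, 51, 10**9)
) -> pd.DataFrame:
    """Per-taxon totals and a size distribution over the unique events."""
    rows = []
    bins = list(size_bins)
    for taxon, grp in unique.groupby("taxon"):
        counts = np.histogram(grp["length"], bins=bins)[0]
        rows.append((taxon, len(grp), int(grp["length"].sum()), *counts.tolist()))
    labels = [
        f"{a}-{b - 1}" if b - 1 > a else f"{a}" for a, b in zip(bins[:-1], bins[1:])
    ]
    return pd.DataFrame(
        rows, columns=["taxon", "n_unique", "total_bp", *labels]
    ).sort_values("taxon", ignore_index=True)
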