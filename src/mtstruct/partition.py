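"""Classification of intergenic sequence by homology cascade.

Intergenic intervals are partitioned per position into four categories,
with fixed precedence:

1. **plastid** — a hit against the plastid database with raw score >= 250
   (reward 5, penalty -4, gap open 8, gap extend 6, word size 7), after
   discarding hits to records on the gene-exclusion list (mitochondrial
   genes with ancient plastid homologs, e.g. atp1/atpA) and hits whose
   query segment has AT content above 72% (near-exclusive false positives
   under such sensitive settings);
2. **mt_conserved** — a hit >= 70 against other plant mitochondrial
   genomes (reward 2, penalty -3, gap open 5, gap extend 2, word size 9),
   over positions not already assigned to plastid;
3. **other_conserved** — a translated (six-frame, BLOSUM62) hit >= 140 or
   a nucleotide hit >= 70 against a general database;
4. **uncharacterized** — everything else.

Raw score = sum of rewards - penalties - gap costs (a gap of length g
costs open + g*extend); no E-value statistics are used. Category kb sums
equal total intergenic kb exactly because assignment is per position.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._seq import at_content, revcomp
from .model import GenomeModel

CATEGORIES = ["plastid", "mt_conserved", "other_conserved", "uncharacterized"]

AT_EXCLUSION_PERCENT = 72.0

# re-exported: AT content of a sequence (ambiguous bases excluded)
__all__ = [
    "ScoringProfile",
    "PLASTID_PROFILE",
    "MT_PROFILE",
    "GENERAL_NT_PROFILE",
    "TRANSLATED_MIN_SCORE",
    "at_content",
    "local_align_score",
    "translated_align_score",
    "classify_intergenic",
    "PartitionResult",
]


@dataclass(frozen=True)
class ScoringProfile:
    """Local-alignment scoring; a gap of length g costs gap_open + g*gap_extend."""

    reward: int
    penalty: int
    gap_open: int
    gap_extend: int
    word_size: int
    min_score: int
    dust: bool = False

    def __post_init__(self) -> None:
        if self.min_score <= 0 or self.reward <= 0:
            raise ValueError("min_score and reward must be positive")


PLASTID_PROFILE = ScoringProfile(5, 4, 8, 6, word_size=7, min_score=250)
MT_PROFILE = ScoringProfile(2, 3, 5, 2, word_size=9, min_score=70)
GENERAL_NT_PROFILE = ScoringProfile(2, 3, 5, 2, word_size=9, min_score=70, dust=True)
TRANSLATED_MIN_SCORE = 140


@dataclass
class Hit:
    query_start: int
    query_end: int
    subject_id: str
    subject_start: int
    subject_end: int
    score: int


def _nt_aligner(profile: ScoringProfile) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = profile.reward
    al.mismatch_score = -profile.penalty
    al.open_gap_score = -(profile.gap_open + profile.gap_extend)
    al.extend_gap_score = -profile.gap_extend
    return al


def _low_complexity(kmer: str, max_bits: float = 1.0) -> bool:
    """Shannon-entropy seed filter standing in for a soft dust mask."""
    counts = {b: kmer.count(b) for b in set(kmer)}
    n = len(kmer)
    h = -sum(c / n * log2(c / n) for c in counts.values())
    return h < max_bits


def _seed_clusters(
    query: str, subject: str, k: int, dust: bool
) -> list[tuple[int, int, int, int]]:
    index: dict[str, list[int]] = {}
    for p in range(len(subject) - k + 1):
        index.setdefault(subject[p : p + k], []).append(p)
    seeds = []
    for p in range(len(query) - k + 1):
        kmer = query[p : p + k]
        if dust and _low_complexity(kmer):
            continue
        for q in index.get(kmer, ()):
            seeds.append((p, q))
    if not seeds:
        return []
    # chain by diagonal band, then along the query
    seeds.sort(key=lambda t: ((t[1] - t[0]) // 32, t[0]))
    clusters = []
    cur = [seeds[0]]
    for s in seeds[1:]:
        band_prev = (cur[-1][1] - cur[-1][0]) // 32
        if (s[1] - s[0]) // 32 != band_prev or s[0] - cur[-1][0] > 200:
            clusters.append(cur)
            cur = []
        cur.append(s)
    clusters.append(cur)
    out = []
    for cl in clusters:
        p1 = [a for a, _ in cl]
        p2 = [b for _, b in cl]
        out.append((min(p1), max(p1) + k, min(p2), max(p2) + k))
    return out


def local_align_score(
    query: str,
    subject_db: dict[str, str],
    profile: ScoringProfile,
    both_strands: bool = True,
) -> list[Hit]:
    """All seed-and-extend local alignments with raw score >= min_score.

    Query coordinates in returned hits always refer to the forward query.
    Queries shorter than the word size yield no hits.
    """
    hits: list[Hit] = []
    if len(query) < profile.word_size:
        return hits
    aligner = _nt_aligner(profile)
    strands = [("+", query)] + ([("-", revcomp(query))] if both_strands else [])
    for sid, subject in subject_db.items():
        for strand, q in strands:
            for q_lo, q_hi, s_lo, s_hi in _seed_clusters(
                q, subject, profile.word_size, profile.dust
            ):
                margin = 20 + (q_hi - q_lo) // 8
                qw = q[max(0, q_lo - margin) : q_hi + margin]
                sw = subject[max(0, s_lo - margin) : s_hi + margin]
                try:
                    best = aligner.align(qw, sw)[0]
                except (IndexError, OverflowError):
                    continue
                if best.score < profile.min_score:
                    continue
                q0 = max(0, q_lo - margin) + best.aligned[0][0][0]
                q1 = max(0, q_lo - margin) + best.aligned[0][-1][1]
                s0 = max(0, s_lo - margin) + best.aligned[1][0][0]
                s1 = max(0, s_lo - margin) + best.aligned[1][-1][1]
                if strand == "-":
                    q0, q1 = len(query) - q1, len(query) - q0
                hits.append(Hit(q0, q1, sid, s0, s1, int(best.score)))
    # deduplicate identical intervals
    seen = set()
    out = []
    for h in sorted(hits, key=lambda h: (-h.score, h.query_start)):
        key = (h.query_start, h.query_end, h.subject_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(h)
    return out


def translated_align_score(
    query: str,
    protein_db: dict[str, str],
    min_score: int = TRANSLATED_MIN_SCORE,
    word_size: int = 4,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[Hit]:
    """Six-frame translated search against a protein database (BLOSUM62).

    Hit coordinates are reported on the nucleotide query. An approximation
    of a protein-level search: exact word seeds, BLOSUM62-scored local
    extension, raw score threshold 140.
    """
    hits: list[Hit] = []
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    n = len(query)
    frames = []
    rc_query = revcomp(query)
    for off in range(3):
        for strand, src in (("+", query), ("-", rc_query)):
            sub = src[off : off + 3 * ((len(src) - off) // 3)]
            frames.append((off, strand, str(Seq(sub).translate())))
    for sid, prot in protein_db.items():
        for off, strand, aa in frames:
            aa = aa.replace("*", "X")
            for q_lo, q_hi, s_lo, s_hi in _seed_clusters(aa, prot, word_size, False):
                margin = 10 + (q_hi - q_lo) // 4
                qw = aa[max(0, q_lo - margin) : q_hi + margin]
                sw = prot[max(0, s_lo - margin) : s_hi + margin]
                try:
                    best = aligner.align(qw, sw)[0]
                except (IndexError, OverflowError, ValueError):
                    continue
                if best.score < min_score:
                    continue
                a0 = max(0, q_lo - margin) + best.aligned[0][0][0]
                a1 = max(0, q_lo - margin) + best.aligned[0][-1][1]
                if strand == "+":
                    q0, q1 = off + 3 * a0, off + 3 * a1
                else:
                    q0, q1 = n - (off + 3 * a1), n - (off + 3 * a0)
                hits.append(Hit(max(0, q0), min(n, q1), sid, 0, 0, int(best.score)))
    return hits


@dataclass
class PartitionResult:
    """Per-position labels plus the category summary table."""

    labels: dict[tuple[str, int, int], np.ndarray]
    summary: pd.DataFrame

    def interval_table(self) -> pd.DataFrame:
        rows = []
        for (cid, start, end), lab in self.labels.items():
            for cat_idx, cat in enumerate(CATEGORIES):
                bp = int((lab == cat_idx).sum())
                if bp:
                    rows.append((cid, start, end, cat, bp))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "category", "bp"])


def classify_intergenic(
    genome: GenomeModel,
    intervals: Sequence[tuple[str, int, int]],
    plastid_db: dict[str, str],
    mt_db: dict[str, str],
    general_nt_db: Optional[dict[str, str]] = None,
    general_prot_db: Optional[dict[str, str]] = None,
    gene_exclusion_list: Sequence[str] = ("atp1", "atpA"),
    at_exclusion: float = AT_EXCLUSION_PERCENT,
) -> PartitionResult:
    """Run the partition cascade over intergenic intervals.

    Each position gets exactly one category; overlapping hits of
    different categories resolve by the fixed precedence plastid >
    mt_conserved > other_conserved > uncharacterized, so the per-category
    kb totals sum to the total intergenic kb exactly.
    """
    excl = set(gene_exclusion_list)
    labels: dict[tuple[str, int, int], np.ndarray] = {}
    for cid, start, end in intervals:
        seq = genome[cid].seq[start:end]
        lab = np.full(len(seq), CATEGORIES.index("uncharacterized"), dtype=np.int8)

        for h in local_align_score(seq, plastid_db, PLASTID_PROFILE):
            if h.subject_id in excl:
                continue
            if at_content(seq[h.query_start : h.query_end]) > at_exclusion:
                continue
            lab[h.query_start : h.query_end] = CATEGORIES.index("plastid")

        plastid_mask = lab == CATEGORIES.index("plastid")
        for h in local_align_score(seq, mt_db, MT_PROFILE):
            sel = np.arange(h.query_start, h.query_end)
            sel = sel[~plastid_mask[sel]]
            lab[sel] = CATEGORIES.index("mt_conserved")

        claimed = lab != CATEGORIES.index("uncharacterized")
        general_hits: list[Hit] = []
        if general_prot_db:
            general_hits.extend(translated_align_score(seq, general_prot_db))
        if general_nt_db:
            general_hits.extend(local_align_score(seq, general_nt_db, GENERAL_NT_PROFILE))
        for h in general_hits:
            sel = np.arange(h.query_start, h.query_end)
            sel = sel[~claimed[sel]]
            lab[sel] = CATEGORIES.index("other_conserved")

        labels[(cid, start, end)] = lab

    total = sum(len(v) for v in labels.values())
    rows = []
    for i, cat in enumerate(CATEGORIES):
        bp = sum(int((v == i).sum()) for v in labels.values())
        rows.append((cat, bp / 1000.0, 100.0 * bp / total if total else 0.0))
    summary = pd.DataFrame(rows, columns=["category", "kb", "percent"])
    return PartitionResult(labels, summary)
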