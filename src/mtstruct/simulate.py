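"""Ground-truthed simulation of multichromosomal circular genomes,
recombinant conformations, and paired-end read libraries.

The generator emulates the statistical structure the downstream analyses
assume: circular chromosomes with planted dispersed-repeat families of
chosen copy number, length, identity and orientation; alternative genome
conformations produced by crossover between two repeat copies (subcircle
fission for direct repeats on one circle, fusion for copies on two circles,
segment inversion for inverted repeats); and paired-end libraries with a
truncated-normal fragment span distribution, uniform substitution errors,
and PCR duplicates emitted as exact fragment re-draws.

Randomness: one seeded :class:`numpy.random.Generator` per entry point;
sub-seeds for internal stages are derived deterministically from it, so a
seed reproduces FASTA/FASTQ output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import array_to_seq, circ_slice, random_seq, revcomp, seq_to_array
from .model import (
    ChromosomeSeq,
    GenomeModel,
    LibrarySpec,
    RepeatCopy,
    RepeatTruth,
)


class InfeasiblePlanError(ValueError):
    """The repeat plan cannot be placed without overlap."""


@dataclass
class RepeatFamilyPlan:
    """Plan for one planted repeat family.

    placements: optional explicit list of (chrom_id, start) or
    (chrom_id, start, strand); when omitted, copies are placed at random
    without overlap, respecting ``min_separation`` between any two planted
    intervals. Orientation 'inverted' puts every copy after the first on
    the minus strand.
    """

    family_id: str
    n_copies: int
    length: int
    identity: float = 1.0
    orientation: str = "direct"
    placements: Optional[list[tuple]] = None
    chroms: Optional[list[str]] = None
    min_separation: int = 500

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise ValueError("a repeat family needs at least two copies")
        if self.length < 30:
            raise ValueError("planted repeats must be at least 30 bp")
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(self.orientation)


def _mutate_to_identity(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute round((1-identity)*L) positions, each to a different base."""
    n_sub = int(round((1.0 - identity) * len(seq)))
    if n_sub == 0:
        return seq
    arr = seq_to_array(seq).copy()
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    alphabet = b"ACGT"
    for p in pos:
        choices = [b for b in alphabet if b != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return array_to_seq(arr)


def generate_genome(
    n_chrom: int,
    length_range: tuple[int, int] | Sequence[int],
    gc: float = 0.45,
    repeat_plan: Sequence[RepeatFamilyPlan] = (),
    seed: int = 0,
) -> GenomeModel:
    """Generate circular chromosomes with planted repeat families.

    ``length_range`` is either (lo, hi) for uniform sampling or an explicit
    list of per-chromosome lengths. Planted copies of a family share one
    random source sequence; each copy is independently mutated down to the
    family's target identity, so two copies at identity q differ from each
    other by roughly 2(1-q). Raises :class:`InfeasiblePlanError` when the
    copies cannot be placed without overlap.
    """
    rng = np.random.default_rng(seed)
    if len(length_range) == 2 and not isinstance(length_range, list):
        lo, hi = length_range
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_chrom)]
    else:
        lengths = [int(x) for x in length_range]
        if len(lengths) != n_chrom:
            raise ValueError("explicit lengths must match n_chrom")

    chrom_ids = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {cid: list(random_seq(rng, n, gc)) for cid, n in zip(chrom_ids, lengths)}
    occupied: dict[str, list[tuple[int, int]]] = {cid: [] for cid in chrom_ids}
    sizes = dict(zip(chrom_ids, lengths))

    def conflicts(cid: str, start: int, end: int, pad: int) -> bool:
        for s, e in occupied[cid]:
            if start < e + pad and s < end + pad:
                return True
        return False

    truths: list[RepeatTruth] = []
    for plan in repeat_plan:
        source = random_seq(rng, plan.length, gc)
        copies: list[RepeatCopy] = []
        if plan.placements is not None:
            if len(plan.placements) != plan.n_copies:
                raise InfeasiblePlanError("placements must match n_copies")
            placed = []
            for k, pl in enumerate(plan.placements):
                cid, start = pl[0], int(pl[1])
                strand = pl[2] if len(pl) > 2 else (
                    "-" if plan.orientation == "inverted" and k > 0 else "+"
                )
                placed.append((cid, start, strand))
        else:
            placed = []
            for k in range(plan.n_copies):
                cid = (
                    plan.chroms[k % len(plan.chroms)]
                    if plan.chroms
                    else chrom_ids[int(rng.integers(n_chrom))]
                )
                strand = "-" if plan.orientation == "inverted" and k > 0 else "+"
                for _ in range(200):
                    start = int(rng.integers(0, sizes[cid] - plan.length))
                    if not conflicts(cid, start, start + plan.length, plan.min_separation):
                        break
                else:
                    raise InfeasiblePlanError(
                        f"cannot place copy {k} of {plan.family_id}"
                    )
                placed.append((cid, start, strand))

        for k, (cid, start, strand) in enumerate(placed):
            end = start + plan.length
            if end > sizes[cid]:
                raise InfeasiblePlanError(
                    f"{plan.family_id}: copy exceeds chromosome bounds"
                )
            if conflicts(cid, start, end, 0):
                raise InfeasiblePlanError(
                    f"{plan.family_id}: overlapping placement on {cid}"
                )
            # first copy stays equal to the source so that the pairwise
            # identity between copy 0 and any later copy is the target
            copy_seq = (
                source if k == 0 else _mutate_to_identity(rng, source, plan.identity)
            )
            if strand == "-":
                copy_seq = revcomp(copy_seq)
            seqs[cid][start:end] = list(copy_seq)
            occupied[cid].append((start, end))
            copies.append(RepeatCopy(cid, start, end, strand))
        truths.append(RepeatTruth(plan.family_id, copies, plan.identity))

    chroms = {cid: ChromosomeSeq(cid, "".join(seqs[cid])) for cid in chrom_ids}
    return GenomeModel(chroms, truths)


def plant_duplicate_pair(
    length: int,
    genome_length: int,
    pos1: int,
    pos2: int,
    seed: int = 0,
    guard_flanks: bool = True,
) -> GenomeModel:
    """One circular chromosome with a perfect duplicate pair of exactly
    ``length`` bp.

    With ``guard_flanks`` the bases immediately flanking the two copies
    are forced to differ between the copies, so the planted duplicate is
    a *maximal* match of exactly the requested length — the construction
    a detection-floor experiment needs (otherwise a chance-matching flank
    base extends the true repeat by one).
    """
    rng = np.random.default_rng(seed)
    bg = list(random_seq(rng, genome_length))
    src = random_seq(rng, length)
    for pos in (pos1, pos2):
        if pos + length > genome_length:
            raise ValueError("copy exceeds chromosome bounds")
        bg[pos : pos + length] = list(src)
    if guard_flanks:
        pairs = [
            ((pos1 - 1) % genome_length, (pos2 - 1) % genome_length),
            ((pos1 + length) % genome_length, (pos2 + length) % genome_length),
        ]
        for i, j in pairs:
            if bg[i] == bg[j]:
                bg[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bg[j]]
    genome = GenomeModel({"chr1": ChromosomeSeq("chr1", "".join(bg))})
    genome.repeat_truth.append(
        RepeatTruth(
            "planted",
            [
                RepeatCopy("chr1", pos1, pos1 + length, "+"),
                RepeatCopy("chr1", pos2, pos2 + length, "+"),
            ],
        )
    )
    return genome


# ---------------------------------------------------------------------------
# Recombinant conformations
# ---------------------------------------------------------------------------

def _oriented_rotation(seq: str, copy: RepeatCopy) -> str:
    """Linearize a circle so the repeat copy, read in its own orientation,
    sits at position 0."""
    if copy.strand == "+":
        return seq[copy.start:] + seq[: copy.start]
    rot = seq[copy.end :] + seq[: copy.end]
    return revcomp(rot)


def derive_recombinants(
    genome: GenomeModel,
    copy_a: RepeatCopy,
    copy_b: RepeatCopy,
    flip_b: bool = False,
) -> GenomeModel:
    """Apply one crossover between two repeat copies by string surgery.

    * direct repeats on one circle -> two subcircles, each keeping one copy;
    * copies on two circles -> one fused circle (re-applying the operation
      to the fused circle regenerates the originals);
    * inverted repeats on one circle -> inversion of the intervening
      segment.

    ``flip_b`` treats copy_b as if it lay on the opposite strand, which is
    how reversed-orientation control products are planted. Copies must have
    equal length. Total base content is conserved exactly (junction bases
    are exchanged, not created).
    """
    ca, cb = copy_a, copy_b
    la = genome[ca.chrom]
    lb = genome[cb.chrom]
    len_a = ca.length(len(la))
    len_b = cb.length(len(lb))
    if len_a != len_b:
        raise ValueError("crossover requires equal-length repeat copies")
    strand_b = cb.strand if not flip_b else ("-" if cb.strand == "+" else "+")
    cb = RepeatCopy(cb.chrom, cb.start, cb.end, strand_b)

    new_chroms = {cid: c for cid, c in genome.chromosomes.items()}

    if ca.chrom != cb.chrom:
        # Fusion: linearize each circle with its copy (oriented) at 0:
        # lin1 = R + X, lin2 = R + Y  ->  fused = R + Y + R + X.
        lin1 = _oriented_rotation(genome[ca.chrom].seq, ca)
        lin2 = _oriented_rotation(genome[cb.chrom].seq, cb)
        fused = lin2 + lin1  # R + Y + R + X (lin2 first keeps R at 0)
        fid = f"{ca.chrom}+{cb.chrom}"
        del new_chroms[ca.chrom]
        del new_chroms[cb.chrom]
        new_chroms[fid] = ChromosomeSeq(fid, fused)
        return GenomeModel(new_chroms, genome.repeat_truth)

    seq = genome[ca.chrom].seq
    n = len(seq)
    # order the two copies along the circle; both branches below assume
    # ca precedes cb with no overlap
    if (cb.start - ca.start) % n > (ca.start - cb.start) % n:
        ca, cb = cb, ca
    if ca.strand == cb.strand:
        # Direct: fission into two subcircles, each keeping one copy.
        sub1 = circ_slice(seq, ca.start, cb.start)
        sub2 = circ_slice(seq, cb.start, ca.start)
        del new_chroms[ca.chrom]
        id1 = f"{ca.chrom}a"
        id2 = f"{ca.chrom}b"
        new_chroms[id1] = ChromosomeSeq(id1, sub1)
        new_chroms[id2] = ChromosomeSeq(id2, sub2)
    else:
        # Inverted: invert the segment between the copies (crossover point
        # inside the repeat; the resulting string is independent of it).
        rot = seq[ca.start:] + seq[: ca.start]  # ca at 0
        a2 = len_a
        b1 = (cb.start - ca.start) % n
        inv = rot[:a2] + revcomp(rot[a2:b1]) + rot[b1:]
        # rotate back so coordinates outside the inverted segment are
        # unchanged relative to the input
        inv = inv[n - ca.start :] + inv[: n - ca.start]
        new_chroms[ca.chrom] = ChromosomeSeq(ca.chrom, inv)
    return GenomeModel(new_chroms, genome.repeat_truth)


# ---------------------------------------------------------------------------
# Paired-end read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadPairSet:
    """Simulated paired-end reads plus their ground-truth table.

    ``truth`` columns: read_id, conf (conformation index), chrom,
    frag_start, span, duplicate (bool), dup_of (read_id or '').
    """

    reads1: list[tuple[str, str]]  # (read_id, sequence)
    reads2: list[tuple[str, str]]
    truth: pd.DataFrame


def _sample_spans(
    rng: np.random.Generator, n: int, library: LibrarySpec
) -> np.ndarray:
    lo, hi = library.span_bounds
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(library.nominal_span, library.span_sd, size=n - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        k = len(ok)
        out[filled : filled + k] = np.round(ok).astype(np.int64)
        filled += k
    return out


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> str:
    if error_rate <= 0:
        return seq
    arr = seq_to_array(seq).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    alphabet = b"ACGT"
    for p in hits:
        choices = [b for b in alphabet if b != arr[p]]
        arr[p] = choices[rng.integers(len(choices))]
    return array_to_seq(arr)


def simulate_read_pairs(
    conformations: Sequence[tuple[GenomeModel, float]],
    library: LibrarySpec,
    n_pairs: int,
    seed: int = 0,
) -> ReadPairSet:
    """Simulate a paired-end library from a mixture of genome conformations.

    Each fragment picks a conformation by mixing weight, a chromosome by
    length, a uniform circular start, and a truncated-normal span; the two
    reads are the fragment's ends (the right read reverse-complemented).
    PCR duplicates are exact re-draws of a previously emitted fragment
    (fresh sequencing errors), emitted at ``library.duplicate_rate``.
    """
    weights = np.array([w for _, w in conformations], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixing weights must sum to 1")
    rng = np.random.default_rng(seed)

    chrom_tables = []
    for gm, _ in conformations:
        cids = list(gm.chromosomes)
        lens = np.array([len(gm[c]) for c in cids], dtype=float)
        chrom_tables.append((cids, lens / lens.sum()))

    rl = library.read_length
    spans = _sample_spans(rng, n_pairs, library)
    conf_idx = rng.choice(len(conformations), size=n_pairs, p=weights)
    dup_draw = rng.random(n_pairs) < library.duplicate_rate

    rows = []
    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    # fragments available for PCR re-draw: (read_id, conf, chrom, start, span)
    emitted: list[tuple[str, int, str, int, int]] = []
    for i in range(n_pairs):
        rid = f"frag{i:07d}"
        if dup_draw[i] and emitted:
            j = int(rng.integers(len(emitted)))
            dup_of, conf, chrom, start, span = emitted[j]
            is_dup = True
        else:
            conf = int(conf_idx[i])
            cids, probs = chrom_tables[conf]
            chrom = cids[int(rng.choice(len(cids), p=probs))]
            seq_len = len(conformations[conf][0][chrom])
            span = int(min(spans[i], seq_len))
            start = int(rng.integers(0, seq_len))
            dup_of = ""
            is_dup = False
            emitted.append((rid, conf, chrom, start, span))
        seq = conformations[conf][0][chrom].seq
        left = circ_slice(seq, start, (start + rl) % len(seq))
        right_start = (start + span - rl) % len(seq)
        right = revcomp(circ_slice(seq, right_start, (right_start + rl) % len(seq)))
        reads1.append((rid, _apply_errors(rng, left, library.error_rate)))
        reads2.append((rid, _apply_errors(rng, right, library.error_rate)))
        rows.append((rid, conf, chrom, start, span, is_dup, dup_of))

    truth = pd.DataFrame(
        rows,
        columns=["read_id", "conf", "chrom", "frag_start", "span", "duplicate", "dup_of"],
    )
    return ReadPairSet(reads1, reads2, truth)
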