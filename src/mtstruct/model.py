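"""Domain types for multichromosomal circular genome analysis.

The central abstractions:

* :class:`GenomeModel` — a set of circular chromosomes, optionally carrying
  planted-repeat ground truth when the genome was simulated.
* :class:`RepeatCopy` / :class:`RepeatPair` — one genomic interval of a
  dispersed repeat, and a pair of intervals found by genome self-comparison.
* :class:`LibrarySpec` / :class:`LibraryWindow` — a paired-end sequencing
  library (nominal fragment span, read length, error and PCR-duplicate
  rates) and the span window inside which a read pair counts as consistent
  with the reference conformation.

Read pairs and repeat catalogs are carried as pandas DataFrames in the
batch APIs; the dataclasses here define the per-record schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._seq import gc_content

# Pair classification labels
CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
DUPLICATE = "duplicate"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


@dataclass
class ChromosomeSeq:
    """One circular chromosome."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"chromosome {self.id} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_content(self.seq)


@dataclass(frozen=True, order=True)
class RepeatCopy:
    """One interval of a repeat: chromosome, 0-based half-open coords, strand.

    end < start denotes an interval wrapping the circular origin.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def length(self, chrom_len: int) -> int:
        return (self.end - self.start) % chrom_len or (self.end - self.start)


@dataclass
class RepeatTruth:
    """Ground truth for one planted repeat family."""

    family_id: str
    copies: list[RepeatCopy]
    target_identity: float = 1.0

    @property
    def n_copies(self) -> int:
        return len(self.copies)


@dataclass
class GenomeModel:
    """A multichromosomal circular genome, with planted truth if simulated."""

    chromosomes: dict[str, ChromosomeSeq]
    repeat_truth: list[RepeatTruth] = field(default_factory=list)

    def __getitem__(self, chrom: str) -> ChromosomeSeq:
        return self.chromosomes[chrom]

    def __iter__(self):
        return iter(self.chromosomes.values())

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self)

    def chrom_lengths(self) -> dict[str, int]:
        return {cid: len(c) for cid, c in self.chromosomes.items()}


@dataclass(frozen=True)
class RepeatPair:
    """Two aligned genomic intervals found by genome self-comparison.

    ``strand`` on copy_b is '-' for inverted repeats; copy_a is always '+'.
    ``identity`` is matches / alignment columns x 100 (gap columns count).
    Pairs are stored with copy_a <= copy_b to deduplicate mirror hits.
    """

    copy_a: RepeatCopy
    copy_b: RepeatCopy
    aligned_length: int
    identity: float
    raw_score: int

    def __post_init__(self) -> None:
        if self.copy_a == self.copy_b:
            raise ValueError("trivial self-pair")
        if self.copy_a > self.copy_b:
            a, b = self.copy_a, self.copy_b
            object.__setattr__(self, "copy_a", b)
            object.__setattr__(self, "copy_b", a)

    @property
    def cross_chromosome(self) -> bool:
        return self.copy_a.chrom != self.copy_b.chrom

    @property
    def inverted(self) -> bool:
        return self.copy_a.strand != self.copy_b.strand


@dataclass
class RepeatCatalog:
    """All repeat pairs from one self-comparison run, plus provenance."""

    pairs: list[RepeatPair]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class LibrarySpec:
    """A paired-end library: nominal span, span window, read length, rates.

    The fragment span distribution is normal with mean ``nominal_span`` and
    SD ``nominal_span / 6``, truncated to [read_length, 3 x nominal_span].
    """

    nominal_span: int
    consistent_window: tuple[int, int]
    read_length: int = 100
    error_rate: float = 0.005
    duplicate_rate: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.consistent_window
        if not (lo < self.nominal_span < hi):
            raise ValueError("window must bracket the nominal span")
        for r in (self.error_rate, self.duplicate_rate):
            if not (0 <= r < 1):
                raise ValueError("rates must lie in [0, 1)")
        if self.read_length > self.nominal_span:
            raise ValueError("read length exceeds nominal fragment span")

    @property
    def span_sd(self) -> float:
        return self.nominal_span / 6.0

    @property
    def span_bounds(self) -> tuple[int, int]:
        return (self.read_length, 3 * self.nominal_span)


# Span windows inside which a properly oriented pair is consistent with the
# reference: 1-6 kb for a nominal 3-kb library, 4-16 kb for a 12-kb library.
LIBRARY_WINDOWS = {
    "3kb": (1_000, 6_000),
    "12kb": (4_000, 16_000),
}


@dataclass(frozen=True)
class LibraryWindow:
    """Consistency span window; edges inclusive."""

    min_bp: int
    max_bp: int
    kind: str = "custom"

    @classmethod
    def from_spec(cls, spec: str) -> "LibraryWindow":
        """Parse '3kb', '12kb', or 'min,max'."""
        if spec in LIBRARY_WINDOWS:
            lo, hi = LIBRARY_WINDOWS[spec]
            return cls(lo, hi, kind=spec)
        lo, hi = (int(x) for x in spec.split(","))
        return cls(lo, hi)

    def contains(self, span: int) -> bool:
        return self.min_bp <= span <= self.max_bp


def library_3kb(**kw) -> LibrarySpec:
    return LibrarySpec(3_000, LIBRARY_WINDOWS["3kb"], **kw)


def library_12kb(**kw) -> LibrarySpec:
    return LibrarySpec(12_000, LIBRARY_WINDOWS["12kb"], **kw)


@dataclass
class AutonomyReport:
    """Structural autonomy verdict for one chromosome."""

    chrom_id: str
    shared_repeats_gt_min: int
    max_recombinant_frequency: Optional[float]
    autonomous: bool
    vacuous: bool = False  # no catalog entry touches this chromosome
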