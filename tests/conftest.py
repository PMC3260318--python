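"""Shared fixtures: ground-truthed simulations reused across test modules.

Heavy objects (the 200-kb assay genome, its read mixtures and mapper) are
session-scoped so the recombination-assay tests and the acceptance tests
share one simulation per condition.
"""

from __future__ import annotations

import numpy as np
import pytest

import mtstruct as M
from mtstruct.model import LibraryWindow

MIXTURE_WEIGHTS = (0.0, 0.02, 0.1, 0.25, 0.5)
ASSAY_N_PAIRS = 15_000
ASSAY_SEED = 42


@pytest.fixture(scope="session")
def assay_genome():
    """200-kb circle with one well-isolated direct 1-kb perfect repeat pair."""
    plan = M.RepeatFamilyPlan(
        "fam1", 2, 1_000, placements=[("chr1", 40_000), ("chr1", 120_000)]
    )
    return M.generate_genome(1, [200_000], repeat_plan=[plan], seed=ASSAY_SEED)


@pytest.fixture(scope="session")
def assay_pair(assay_genome):
    cat = M.find_exact_repeats(assay_genome, 30)
    pairs = [p for p in cat if p.aligned_length == 1_000]
    assert len(pairs) == 1
    return pairs[0]


@pytest.fixture(scope="session")
def assay_variant(assay_genome):
    t = assay_genome.repeat_truth[0]
    return M.derive_recombinants(assay_genome, t.copies[0], t.copies[1])


@pytest.fixture(scope="session")
def assay_inverted_variant(assay_genome):
    """Inverted-type crossover product of the direct pair (control target)."""
    t = assay_genome.repeat_truth[0]
    return M.derive_recombinants(
        assay_genome, t.copies[0], t.copies[1], flip_b=True
    )


@pytest.fixture(scope="session")
def library():
    return M.library_3kb()


@pytest.fixture(scope="session")
def window():
    return LibraryWindow.from_spec("3kb")


@pytest.fixture(scope="session")
def assay_mapper(assay_genome):
    return M.ReadMapper(assay_genome)


@pytest.fixture(scope="session")
def labelled_mixtures(assay_genome, assay_variant, library, window, assay_mapper):
    """Classified pair tables for the reference/recombinant mixtures."""
    out = {}
    for i, wt in enumerate(MIXTURE_WEIGHTS):
        reads = M.simulate_read_pairs(
            [(assay_genome, 1 - wt), (assay_variant, wt)],
            library,
            ASSAY_N_PAIRS,
            seed=100 + i,
        )
        pairs = M.map_reads(reads.reads1, reads.reads2, assay_genome, assay_mapper)
        out[wt] = M.classify(M.deduplicate(pairs), window, assay_genome)
    return out


@pytest.fixture(scope="session")
def labelled_inverted_mixture(
    assay_genome, assay_inverted_variant, library, window, assay_mapper
):
    reads = M.simulate_read_pairs(
        [(assay_genome, 0.7), (assay_inverted_variant, 0.3)],
        library,
        ASSAY_N_PAIRS,
        seed=55,
    )
    pairs = M.map_reads(reads.reads1, reads.reads2, assay_genome, assay_mapper)
    return M.classify(M.deduplicate(pairs), window, assay_genome)


def binomial_3se(w: float, n: int) -> float:
    return 3 * np.sqrt(max(w * (1 - w), 1e-12) / n)
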