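#!/usr/bin/env python
"""Simulate the study system: a six-chromosome circular mitochondrial-style
genome with planted repeat families, its recombinant conformations, and a
3-kb paired-end library sampled from a conformation mixture.

Writes results/sim/: genome.fasta, reads.1.fastq, reads.2.fastq, truth.tsv.

Design: chr1/chr2 share only a short (80 bp) repeat and no recombinant
conformation is simulated for it (structurally autonomous circles);
chr3+chr4 and chr5+chr6 each share a large repeat whose fused single-circle
conformation makes up 20% of the library each. A 100-bp imperfect family
inside chr3 adds repeat-landscape texture.
"""

from pathlib import Path

import mtstruct as M
from mtstruct import io

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 21

PLANS = [
    M.RepeatFamilyPlan("short12", 2, 80, placements=[("chr1", 8_000), ("chr2", 9_000)]),
    M.RepeatFamilyPlan("shared34", 2, 1_000, placements=[("chr3", 10_000), ("chr4", 15_000)]),
    M.RepeatFamilyPlan("shared56", 2, 2_000, placements=[("chr5", 12_000), ("chr6", 8_000)]),
    M.RepeatFamilyPlan(
        "divergent3", 2, 100, identity=0.96,
        placements=[("chr3", 25_000), ("chr3", 31_000)],
    ),
]
LENGTHS = [30_000, 25_000, 35_000, 30_000, 32_000, 28_000]
N_PAIRS = 25_000


def build_genome():
    return M.generate_genome(6, LENGTHS, repeat_plan=PLANS, seed=SEED)


def build_mixture(genome):
    fused34 = M.derive_recombinants(genome, *genome.repeat_truth[1].copies)
    fused56 = M.derive_recombinants(genome, *genome.repeat_truth[2].copies)
    return [(genome, 0.6), (fused34, 0.2), (fused56, 0.2)]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = build_genome()
    mixture = build_mixture(genome)
    library = M.library_3kb()
    reads = M.simulate_read_pairs(mixture, library, N_PAIRS, seed=SEED + 56)

    io.write_genome_fasta(genome, OUT / "genome.fasta")
    io.write_fastq_pair(reads, OUT / "reads")
    io.write_truth_table(reads, OUT / "truth.tsv")

    n_dup = int(reads.truth["duplicate"].sum())
    print(f"genome: {len(genome.chromosomes)} circular chromosomes, "
          f"{genome.total_length:,} bp, {len(genome.repeat_truth)} planted families")
    print(f"library: {N_PAIRS:,} read pairs ({n_dup} PCR duplicates), "
          f"mixture weights 0.6 reference / 0.2 fused(chr3+4) / 0.2 fused(chr5+6)")
    print(f"wrote {OUT}/genome.fasta, reads.[12].fastq, truth.tsv")


if __name__ == "__main__":
    main()
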