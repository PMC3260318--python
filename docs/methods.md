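# Methods

## The assay model

A dispersed repeat with two copies A and B partitions its neighbourhood
into four junction environments. Writing LF/RF for the flank upstream and
downstream of a copy *in that copy's reading orientation*:

* Reference 1: LF(A) — repeat — RF(A)
* Reference 2: LF(B) — repeat — RF(B)
* Recombinant 1: LF(B) — repeat — RF(A)
* Recombinant 2: LF(A) — repeat — RF(B)

Crossover between the copies exchanges flanks, which is exactly the
junction structure of the recombinant environments: for direct repeats on
one circle the products are two subcircles (each keeping one copy), for
copies on two circles a single fused circle, and for inverted repeats an
inversion of the intervening segment. A paired-end fragment spanning a
repeat copy — one read wholly in each flank, proper inward orientation,
span inside the library window — votes for the environment whose flank
pair it connects. Support counts (C1, C2, R1, R2) give the
recombinant-conformation frequency

    f = (R1 + R2) / (C1 + C2 + R1 + R2),

reported to 4 decimals in tables and rounded half-up for percent display.
Counting is implemented as a coordinate transform from reference mapping
positions into environment coordinates, so reference-mapped reads are
never re-aligned; reads overlapping the repeat interval itself are
excluded (they cannot discriminate environments), as are PCR duplicates
and ambiguous (multi-locus) placements. The same machinery runs the
reversed-orientation control: flipping one copy's annotated orientation
builds environments that only inverted-orientation products can support,
so on direct-repeat recombination the control measures the chimera and
artifact floor — exactly zero in chimera-free simulations.

Repeats at least half the window span long leave little room for two
flanking reads; repeats at or beyond the window span cannot be assayed at
all and raise an explicit error rather than returning zero counts.

## Classification rules

A mapped pair is consistent with the reference conformation iff both ends
are on one chromosome, one read maps forward and the other reverse, and
the circular arc from the forward read's start to the reverse read's end
lies inside the library window, edges inclusive. Window defaults are
1–6 kb for a nominal 3-kb library and 4–16 kb for a 12-kb library. The
strict-then-reclassify two-step used with historical mappers collapses to
this single windowed test, which is what we implement. Cross-chromosome
and same-strand pairs are inconsistent; duplicate removal keys on the
start positions of both ends with end order ignored.

On a circle any forward/reverse pair is inward-facing along one of the
two arcs; the span is measured along that arc. Outward-type artifacts
therefore appear as spans near the chromosome length and fall outside the
window.

## Eligibility filters

Applied to the repeat catalog before assaying, in order, each with a
recorded reason: (a) length < 50 bp or identity < 95%; (b) copies
separated by less than the maximum library span (shorter circular gap
between the copies); (c) a correlated pair of larger repeats with one
copy within the maximum span of each focal copy — this operationalization
of "correlated" is an interpretation and is exposed as a togglable rule;
(d) optionally, for short-span libraries, a focal copy within 100 bp of
the start of any other repeat copy belonging to a pair > 500 bp;
(e) after counting, at least five consistent pairs spanning each copy
(C1 and C2 separately), otherwise the frequency is undefined rather than
zero; (f) optionally a seeded random retention of 5% of pairs shorter
than 200 bp, for catalogs dominated by small repeats.

## Repeat detection

`find_exact_repeats` reports maximal exact pairs (extendable in neither
direction) at or above a length threshold, on both strands, within and
between chromosomes, by k-mer seeding (k = threshold) with left-maximality
filtering and circular extension capped at one genome length. A perfectly
periodic circle (every rotation matching) is the one degenerate case not
reported. Linear sequences are honoured when a chromosome is flagged
non-circular.

`find_repeat_pairs` is a seed-and-extend local aligner: 11-mer seeds,
diagonal-band chaining, and banded local alignment of candidate windows
(Biopython's PairwiseAligner) under match +1, mismatch −2, gap open −5,
gap extend −2, with hits kept at raw score ≥ 30. These defaults are
chosen so the minimal reportable perfect repeat is exactly 30 bp; all
five parameters are configurable. Identity is matches / alignment columns
(gaps count as columns). Because the aligner is local, terminal
mismatches of a planted imperfect repeat may be trimmed, so measured
identity can sit up to about a point above the planted value. Candidate
windows wider than 12 kb are skipped (such giant repeats are still
reported by the exact finder); overlapping hits are reported as distinct
pairs, with no chaining or merging, and only identical-interval self-hits
are excluded.

Coverage, depth-curve and pair statistics are per-position bookkeeping
over pair intervals: coverage is the union of qualifying intervals (with
the large/small split at 1 kb), the depth curve at d is the fraction of
positions covered by at most d−1 pair intervals (its first value is the
single-copy fraction), and statistics are over pairs, not copies — a
four-copy family yields six pairs, so summed pair length can exceed the
genome length in highly multicopy designs.

## The simulator

`generate_genome` plants repeat families into random circular chromosomes
at explicit or random non-overlapping positions; each family's first copy
equals the source sequence and later copies are mutated down to the
target identity, so pairwise identity between copy 0 and any later copy
matches the target (one substitution's worth of tolerance).
`derive_recombinants` produces crossover products by string surgery;
re-applying it to a fused circle regenerates the original circles, and a
`flip_b` override plants inverted-type products of a direct pair for
control validation. `simulate_read_pairs` draws fragments from a
conformation mixture: conformation by weight, chromosome by length,
uniform circular start, span from a normal distribution with mean equal
to the nominal span and SD = span/6, truncated to [read length,
3 × span] — a unimodal spread consistent with the classification windows;
the nominal spans themselves (3 or 12 kb) are the field-standard library
sizes. Reads are the fragment ends (right end reverse-complemented),
wrap the origin, carry independent uniform substitution errors, and PCR
duplicates are exact fragment re-draws (fresh sequencing errors) at the
configured rate, matching the deduplication criterion downstream.
Defaults: read length 100 bp, error rate 0.005, duplicate rate 0.05.
Indels and platform-specific quality profiles are not simulated: the
assay consumes mapping positions, not base identities, so substitution
errors are the relevant perturbation. One seeded generator drives each
entry point; identical seeds give byte-identical FASTA/FASTQ.

The simulations used throughout the tests and drivers are desk-scale by
design: 25–200 kb circles, 8,000–25,000 read pairs, chosen to give a few
hundred junction-spanning pairs per assayed repeat — enough that binomial
error bands around the planted mixing weights are a few percentage
points. What passing these tests shows is that the estimators are
unbiased and correctly calibrated on data matching their model
assumptions; they do not probe real-data complications such as
heteroplasmy, mapping reference bias from diverged repeats, chimeric
library artifacts (the control exists to measure exactly those), or
homopolymer indel errors.

## Read placement

The mapper is deliberately simple and deterministic: exact 20-mer seeds
at three offsets per read (both strands), Hamming scoring of candidate
placements against the doubled chromosome sequence (circularity without
wraps), mismatch budget 12% of the read length, and an ambiguity rule —
two distinct equally-good placements make the read ambiguous, which
removes repeat-internal reads from every count, numerator and
denominator alike. SAM-style ingestion recomputes orientation and span
from coordinate fields rather than trusting stored flags, keeping the
classification rules self-contained.

## Partition cascade

Per-position category assignment with fixed precedence plastid >
mt-conserved > other-conserved > uncharacterized guarantees exact
conservation of category totals (coverage in kb requires positional
bookkeeping; an interval can legitimately split between categories).
Profiles: plastid reward 5 / penalty 4 / gap 8+6g / word 7 / min 250
with a gene-exclusion ID list (default atp1/atpA) and the AT > 72% hit
filter, computed over the hit (not the whole interval — a documented
choice); mt and general nucleotide searches reward 2 / penalty 3 /
gap 5+2g / word 9 / min 70; the general nucleotide search applies an
entropy-based seed filter standing in for a soft dust mask; the
translated search is six-frame × BLOSUM62 at min 140 (word size 4,
gaps 11+1g) — an approximation of a protein-level database search. Raw
scores, not E-values, are the thresholds throughout.

## Indel census

Events are maximal per-taxon gap-column runs outside masked ranges
(unalignable gene ends); runs clipped by a mask edge are flagged.
Polarity against a designated outgroup: deletion when the outgroup has
sequence across the run, insertion (carried by the non-gapped taxa) when
the outgroup is entirely gapped, undetermined otherwise — undetermined
events still count, since the census reports indels, not polarity. An
event is unique to its taxon iff no other taxon's event overlaps it,
single shared columns included (the strictest reading of
non-overlapping); events spanning feature boundaries are counted once.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open; circular intervals may wrap, stored
with end < start. Window edges are inclusive. Frequencies with zero total
support are undefined (None), never 0. Chromosomes absent from the repeat
catalog are vacuously autonomous and flagged as such. A fully
repeat-masked chromosome is excluded from the depth-evenness ratio and
flagged. Collapse diagnostics flag intervals with windowed depth at least
twice the chromosome median *and* at least three inconsistent pair ends
within 1 kb of the interval boundaries — both signatures are required, so
a genuine autonomous subcircle (even depth, no boundary conflicts)
is never flagged.
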