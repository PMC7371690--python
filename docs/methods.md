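# Methods

## Coordinate model

All coordinates are 1-based and fully inclusive on the heavy (H) strand,
as GenBank-style mitogenome ledgers print them. Circularity is expressed
by `start > end` (the feature wraps the origin); lengths, slices and
position unions are computed over the covered position set, so a wrapping
feature of length L−start+1+end behaves exactly like any other. Light
(L)-strand features are analyzed on their coding strand, i.e. the reverse
complement of the H-strand slice. Sequences may contain N; those
positions are excluded from every composition denominator.

## Structural ledger

The adjacency ledger pairs each feature (sorted by start) with its
successor, closing the circle from the last feature back to the first.
The signed gap is `next.start − prev.end − 1`: positive values are
intergenic spacers, negative values overlaps, zero abutment. This yields
a conservation law used as a property test: signed gaps plus feature
lengths always sum to the genome length. Summary counts of spacer
regions and overlap locations include only non-zero gaps, which is how
such ledgers are conventionally tallied (the circular closure in the
bovid layout is an exact abutment and is therefore counted in neither).
A feature fully contained in its predecessor (not observed in bovids) is
skipped with a warning rather than producing a negative gap larger than
the feature.

The protein-coding fraction of the genome divides the *union* of PCG
positions by the genome length — overlapping positions are counted once,
which is what makes the bovid value 11,339/16,345 = 69.37 % rather than
the naive 11,404 sum; the sum-based figure remains available
(`pcg_fraction_from_sum`).

Protein-coding genes are additionally frame-checked when the sequence is
present: start codon membership in the genetic code's start set, the
terminal state (complete stop; incomplete `T`/`TA`, completed to UAA by
polyadenylation in vertebrate mitochondria; or none), and a count of
in-frame internal stops. These are reports, not failures — annotation
pipelines disagree routinely, and the caller decides on strictness.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C). Both are scale invariant,
so counts and percentages give identical values (a tested property). A
zero denominator yields 0.0 with an explicit flag instead of an
exception, because class-level profiles of real annotations can hit
GC-free slices. Percentages are reported to 1 decimal and skews to 3
decimals; raw values are retained in machine output. Note that skews
recomputed from *rounded* percentages can differ from count-based skews
in the third decimal (for the bovid whole-genome figures: −0.318 vs
−0.319); comparisons against published skews therefore use a 0.0015
tolerance.

Class profiles concatenate member genes' coding-strand sequences, so a
position inside a gene overlap contributes once per gene — the right
convention for codon-level analyses. A union-based alternative exists
behind a flag.

## Codon usage

Codons are read in frame from position 1 of each PCG's coding sequence;
a trailing 1–2 nt incomplete stop is dropped, and a terminal complete
stop codon is excluded by default (the common MEGA-style convention; an
`include_stops` switch flips it). RSCU follows the standard definition
RSCU_i = k·X_i/Σ_family X with families derived from the genetic code —
under transl_table 2, arginine is the four-codon CGN box because AGA/AGG
are stops. Families with zero usage report RSCU 0 and are flagged rather
than dividing by zero.

## Motifs

Motif scanning counts overlapping occurrences, case-insensitively. There
is no universal counting convention for dispersed control-region motifs;
counting every occurrence is the conservative superset and the report
says so. The terminal poly-C statistic is the maximal C-run ending at
the region's last position.

## Distances and AMOVA

Pairwise comparisons skip sites where either row is a gap or ambiguity
("pairwise deletion", default); "complete deletion" drops a site from
all pairs if any row is ambiguous there, matching MEGA's default, and is
available since published divergences rarely state the choice.
Transitions are A↔G and C↔T; K2P is d = −½·ln((1−2P−Q)√(1−2Q)), with an
infinity flag on domain violations rather than an exception. Group
divergence is the mean of all between-group pairwise distances, with the
model selectable (p-distance default — the published value's model is
typically unstated, and at these divergences the models agree to the
printed precision).

AMOVA uses squared pairwise substitution counts as the distance (the
Arlequin default for haplotype data) and the standard one-level
estimators: SSD_total = (1/N)·Σ d²; SSD_within = Σ_g (1/n_g)·Σ_in-g d²;
σ²_w = SSD_within/(N−G); σ²_a = (SSD_among/(G−1) − σ²_w)/n̄ with the
unequal-size coefficient n̄ = (N − Σn_g²/N)/(G−1). Negative components
are reported as-is with a flag (standard AMOVA behavior near zero
structure). The permutation p-value counts the observed configuration:
p = (1 + #{perm Φ ≥ Φ_obs})/(B+1), with B = 1000 by default and a
required seed in the CLI.

## Trees

Neighbor joining implements the Saitou–Nei Q-criterion with deterministic
tie-breaking (lexicographically smallest pair of cluster representative
labels); negative branch lengths are clamped to zero. On additive
matrices the generating topology and branch lengths are recovered
exactly (tested to 1e-9), and the topology agrees with an independent NJ
implementation. Parsimony scoring uses the unit-cost Sankoff recursion
(exact for multifurcating trees and invariant under rooting, both
tested); the exhaustive search enumerates unrooted topologies by
stepwise insertion and is capped at 9 taxa (135,135 topologies) —
beyond that NJ is the intended tool. Bootstrap support is the percentage
of site-resampled replicates containing each internal bipartition of the
point tree; the default of 100 replicates is a desk-scale choice
(publication analyses often use thousands; the count is configurable).
Bayesian inference is deliberately out of scope: for the clade-level
questions this package answers, distance and parsimony topologies with
bootstrap support carry the comparison.

## Synthetic data

`bovid_table1` mode reuses the packaged gaur coordinates, so every
coordinate-derived statistic equals the reference ledger by
construction; `random` mode tiles a circle with a non-pathological
random layout for property tests. Sequences are drawn i.i.d. from the
target composition (default A .335, T .272, C .259, G .134). When coding
constraints are on (default), PCGs are then repaired to have ATG starts,
complete or incomplete terminal stops matching their length mod 3, and
no internal stops; because overlapping genes constrain each other the
repair iterates to a joint fixed point. The repair touches a few hundred
positions, so the realized composition sits slightly off the i.i.d.
target — the 3-standard-error composition check applies to unconstrained
draws. TACAT/ATGTA copies (default 4 each; published descriptions say
"multiple copies" without a count) are planted without overlap in the
control region, and the region ends in an exactly 13-C run (the base
before the run is forced non-C so the planted length is the measured
length). Background sequence can contain additional chance motif hits,
so tests assert exact counts only on constructed motif-free backgrounds.

Haplotypes: each group descends from a group ancestor placed
`group_divergence_from_base[label]` substitutions from the base genome
(defaults 0/304/634 — the magnitudes of the emulated study, with the
focal group ancestral); members carry ⌈w/2⌉ or ⌊w/2⌋ private
substitutions alternately so that pairwise within-group counts average
the target w (default 33; exactly w for adjacent-parity pairs and for
2-member groups). In `exact` mode all mutated sites are disjoint, making
every pairwise count deterministic; `poisson` mode draws per-branch
counts for statistical tests. No indels are simulated — the emulated
genomes are length-identical — and no selection or rate heterogeneity,
so passing tests demonstrate correctness of the estimators on
substitution-only data, not robustness to alignment error or
heterotachy in real genomes.

Group-level substitution counts (e.g. the 304/634 design values) are
recovered in reports by comparing group majority-consensus sequences,
which removes the private-substitution inflation that individual
pairwise counts carry.

## Problem sizes and determinism

Default test and report scales are desk-sized: 16.3 kb genomes, ≤ 8
haplotypes, 100 bootstrap replicates, 1000 AMOVA permutations (fewer in
tests), 20-seed recovery checks. Every stochastic stage takes an
explicit seed, recorded in manifests; identical seeds yield byte-identical
output bundles (a tested contract, enabled by checksum-based rather than
timestamp-based provenance).
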