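# Methods

This note documents the models, formulas, defaults and numerical choices
behind `ystrkit`, and what its simulation-based tests do and do not show.

## Data model

A haplotype table is a samples × loci grid of allele calls over a
23-locus panel (the PowerPlex Y23 set: 17 typical Y-STR markers plus 6
rapidly mutating loci). Three call pathologies seen in real capillary
electrophoresis data are first-class states:

- **null** — no amplification (e.g., deletions at DYS448); canonical
  token `0`, with `-` and `null` accepted on input;
- **microvariant** — fractional repeats with fractional part .1/.2/.3
  (e.g., 13.2), preserved on I/O;
- **duplicated** — two alleles at a nominally single-copy locus (e.g.,
  DYS19 duplications), stored as a sorted pair.

DYS385 is the panel's only true multi-copy locus; its two copies cannot
be assigned to chromosomes, so it is stored as an unordered pair (a ≤ b)
and compared as such. DYS389II is stored exactly as reported (not
decomposed as DYS389II − DYS389I), since genotypers report it that way and
any recoding is lossy. Allele ranges in the panel definitions are
validation envelopes around the commercial ladder ranges, not population
assumptions.

## Diversity and forensic statistics

For a frequency spectrum with counts c₁…c_k, n = Σcᵢ, pᵢ = cᵢ/n:

- Nei's unbiased diversity HD = n(1 − Σpᵢ²)/(n − 1);
- match probability HMP = Σpᵢ² (so HMP = 1 − (n−1)/n·HD, an identity the
  suite checks to 1e−12);
- discrimination capacity k/n; unique fraction = (#singletons)/n.

Per-locus forensic parameters use the allele spectrum with **nulls
excluded** (a null is absence of data, not an allele; `null_as_allele`
offers the alternative) and **duplications contributing both alleles**.
GD is the same unbiased formula on allele frequencies; RMP = Σp²;
PD = 1 − RMP; PIC = 1 − Σp² − (Σp²)² + Σp⁴. PE and TPI use the
conventional diploid formulas adapted to haploid data with h = GD,
H = 1 − h: PE = h²(1 − 2hH²), TPI = 1/(2H). This haploid adaptation is a
convention, flagged here because Y-STR data have no true heterozygosity.

For exact haplotype matching, duplications make a haplotype distinct
(exact-token comparison), and nulls compare equal to nulls.

## Step distances, R_ST and Nei distance

Mutational-step distances operate on single-copy loci only — DYS385 is
excluded from all step-based computations because its copies cannot be
paired across individuals. Microvariants are rounded half-up to the
nearest integer first. Nulls and duplications are handled by pairwise
deletion per locus pair (listwise deletion available); the choice is a
package decision, as published pipelines rarely state theirs.

The default step/R_ST locus set is the 17 typical markers minus DYS385a/b
(15 loci), mirroring the common "17-marker" comparative convention while
respecting the DYS385 exclusion; any locus subset can be passed
explicitly, including the full 21 single-copy loci.

R_ST is the among-population variance fraction from a one-level AMOVA on
squared-step distances, reported unclamped (slightly negative values are
meaningful evidence of no differentiation). Nei's standard distance is
D = −ln(J_AB/√(J_A·J_B)) with per-locus homozygosities averaged
arithmetically over loci (Nei 1972); populations sharing no alleles
anywhere give D = +∞, which neighbor joining rejects with advice rather
than silently patching.

## AMOVA

Sums of squares follow the distance-matrix formulation
SSD(S) = Σᵢⱼ d²ᵢⱼ/(2|S|); variance components come from equating mean
squares to expectations with the standard unequal-n coefficients (written
out in the module docstring). Φ-statistics: F_ST, F_SC, F_CT. Negative
components and negative F_CT are reported as computed — truncation would
hide exactly the "no geographic structure" signal the statistic exists to
express.

Permutation inference permutes samples among populations for F_ST
(globally) and F_SC (within groups), and whole populations among groups
for F_CT, with p = (#{perm ≥ obs} + 1)/(n_perm + 1). When fewer distinct
rearrangements exist than permutations requested, the test switches to
exhaustive enumeration and returns the exact fraction. The CLI default is
9,999 permutations and a mandatory seed.

## Median-joining networks

Input preparation rounds microvariants half-up, drops DYS385, collapses
identical rows with multiplicities, and by default drops samples carrying
a null or duplication at a retained locus (an ordered state space cannot
encode absence); `drop-locus` removes the offending loci table-wide
instead.

Construction: (1) the ε-relaxed minimum spanning network via a
single-linkage sweep — at each merge, all inter-component links within ε
of the minimal inter-component distance are added (ε = 0 is the plain
MSN, the union of all MSTs, and the default since published analyses
rarely state ε); (2) quasi-medians of connected triples (coordinate-wise
medians) are added whenever they reduce the cost of a minimum spanning
tree over the node set, iterated to a fixed point with a 50-round cap
(exceeding the cap is an error, never silent truncation); (3) inferred
medians of degree ≤ 2 lying on no shortest path between sampled nodes are
deleted, iteratively.

Determinism: nodes are processed in lexicographic order and equal-cost
candidate medians are added lexicographically smallest first. MJ output
is order-sensitive in general; fixing the order makes runs reproducible.
All loci are weighted equally.

Desk-scale guarantees checked by the suite: the final network spans all
sampled haplotypes at a connection cost never above their MST; on tiny
inputs (≤ 6 haplotypes × ≤ 4 loci) the network length meets a brute-force
Steiner minimum computed over the bounding integer lattice, with equality
on tree-like data; genealogies simulated without homoplasy are recovered
edge-for-edge.

## Rho-statistic TMRCA

ρ = mean absolute step distance from a root haplotype to each cluster
member; σ = √(ρ/n) under the star-genealogy approximation (the full
branch-weighted variance is out of scope and would require the genealogy
itself). The root defaults to the cluster modal haplotype — the usual
choice when the founder node is the network hub — with ties broken toward
the cluster median allele, then the smaller value; an explicit root can
be supplied. Scaling: T = ρ/(μL) generations, μ = 2.1 × 10⁻³ per locus
per generation, 30-year generations, L = loci actually used (21 for the
default network set, so the distances match network edge lengths).

Calibration note: the strict SMM introduces mild homoplasy (a +1 followed
by −1 leaves no trace), so ρ slightly underestimates the mutation count;
at T = 1000 y over 21 loci the bias is ~3–4%, well inside the 10%
recovery tolerance the suite enforces over 200 simulated clusters.

## The simulator

`simulate_tribe` emulates a clan-structured patrilineal sampling design:
each clan descends from one or more founder haplotypes drawn uniformly
within locus allele ranges, sampled T years later. Defaults are the study
conditions the package is tested under: 7 clans at sizes
40/32/39/85/36/53/65 (n = 350), one founder per clan, T = 1000 years,
μ = 2.1 × 10⁻³, 30-year generations, star genealogies, no admixture or
call noise. Mutation is strict single-step ±1 (Poisson counts per locus,
reflected at the allele-range bounds) — deliberately the same model under
which rho dating is calibrated. Options: multi-founder clans, inter-clan
admixture at a configurable rate, Kingman-coalescent genealogies rescaled
so the root sits at T, and null/duplication noise injection for I/O
robustness tests. All randomness flows from one integer seed.

What the simulator does **not** emulate: real founder haplotypes are
phylogenetically correlated (uniform draws make founders far more
distant than real clans, so simulated F_ST values are much higher than
those of real tribes), mutation rates vary across loci, populations grow
and shrink, and genealogies are neither purely star nor single-population
Kingman. Passing tests therefore demonstrate the correctness of the
statistics and their implementations under a known model — not that real
data will show the same effect sizes.

## Trees and ordination

Neighbor joining follows the Saitou–Nei Q-criterion; negative branch
lengths are clamped to zero with the excess moved to the sibling branch,
preserving the joined pair's path length. Newick is the only output
format, branch lengths to 6 significant digits. Classical MDS is
Torgerson double-centering with an eigendecomposition; eigenvalues are
returned so callers can see distortion, k is reduced (with a warning)
when positive eigenvalues run out, and each axis is sign-fixed by making
its largest-magnitude coordinate positive so plots are reproducible.

## Problem sizes used in the verification suite

Published-value checks run on the bundled frequency table (exact, < 1 s).
Oracle comparisons use 4 populations × 6 samples (AMOVA), 2 × 50 samples
(R_ST equivalence), and ≤ 10 haplotypes (networks, including brute-force
Steiner search over the bounding lattice). Parameter recovery uses 200
star clusters of 40 lineages over 21 loci; structure signatures use the
full 7-clan, n = 350 design and 12 structureless replicates of n = 105.
These sizes make every oracle exhaustively computable while keeping the
whole suite under a minute of CPU.

## Known limitations

- PE/TPI are haploid adaptations of diploid formulas; interpret
  comparatively, not probabilistically.
- The rho σ ignores genealogy correlation (star approximation) and the
  modal-root choice adds a small downward bias when the founder allele is
  not modal.
- The MJ implementation targets the standard ε-MSN + quasi-median
  construction; the maximum-parsimony post-processing step of some
  network tools is not implemented.
- AMOVA assumes squared distances; feeding unsquared matrices is an
  error, not a warning.
- No confidence intervals for HD, and no haplotype-frequency surveying
  against external reference databases.
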