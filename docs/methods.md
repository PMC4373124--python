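# Methods

This note documents the models, estimators and numerical choices behind
`haplotrace`, and what the synthetic fixtures do and do not establish.

## Haplogroup calling on SNP trees

A haplogroup tree is a rooted tree of labelled nodes; each non-root node
may carry one or more binary markers whose derived allele defines it.  The
caller assigns the deepest node with a typed derived path-defining marker,
subject to two consistency rules: derived alleles on incomparable branches
are a genotyping conflict (an error naming both markers, not a majority
vote — array-based panels treat such patterns as assay failure), and a
typed ancestral marker upstream of a derived one is likewise a conflict.
Missing markers on the accepted path are tolerated when a deeper typed
derived marker supports the call, since real panels have dropouts.  The
paragroup flag (`C*`) is set when at least one child-defining marker was
typed and every typed child-defining marker is ancestral; a sample
ancestral for everything is the root paragroup.  Calling is independent of
marker listing order by construction (the call depends only on the state
map).

## mtDNA control-region analysis

Coordinates are 1-based on a circular reference of length 16,569 (rCRS
numbering); the default HVS-I comparison window is 16051–16365,
configurable, since exact amplicon endpoints vary between studies.
Sequences are aligned to the reference window by global Needleman–Wunsch
(match +1, mismatch −1, linear gap −2 by default — adequate at control-
region divergence and configurable), via Biopython's `PairwiseAligner`.
Variants are reported as substitutions or single-base indels; indels are
shifted to their 3'-most equivalent position through homopolymer runs,
following mtDNA nomenclature convention.  An alignment identity below 0.8
raises a quality error (wrong-region safeguard).  Multi-base indel
normalisation beyond single-base toys is out of scope.

Motif detection is a total three-valued function: *present* when every
required variant lying in an assayed region is observed and no required
variant falls in an unassayed region; *undetermined* when all assayed
requirements match but some requirement lies in an unassayed region (e.g.
the coding-region site 14,022 when only HVS-I was sequenced); *absent*
otherwise.  The Malagasy motif is encoded as the three control-region
variants (16217C, 16247G, 16261T) plus the coding sites 1,473 and 3,423;
since the defining publications report the sites rather than the alleles,
placeholder T>C alleles are used and documented in the code.

Haplogroup classification uses a miniature motif table: each haplogroup
maps to a cumulative set of diagnostic (position, derived-allele) pairs,
child sets containing parent sets; the deepest fully-matched entry wins,
with equal-depth ties broken lexicographically and flagged ambiguous, and
no match returning the reference (root) label.  This is deliberately a
small, exact classifier, not a re-implementation of fluctuation-scored
database classifiers; heteroplasmy and quality trimming are out of scope.

Haplotype sharing between two populations counts distinct identical
variant sets within the comparison window; sequences whose declared window
does not cover the comparison window are excluded with a logged count
(mirroring the practice of dropping shorter published amplicons), and a
population with no usable sequence is an error.

## Haploid AMOVA F_ST and permutation testing

With inter-individual distance δ = 1 for different haplogroups and 0
otherwise, the two-population components are

    SSD_within(i) = (n_i² − Σ_k c_ik²) / (2 n_i)
    SSD_total     = the same on pooled counts
    SSD_among     = SSD_total − SSD_within
    n_c = (N − Σ_i n_i²/N) / (P−1),  P = 2
    σ²_a = (MSD_among − MSD_within) / n_c,   σ²_w = MSD_within
    F_ST = σ²_a / (σ²_a + σ²_w)    (0 when the denominator vanishes)

This is the haplotype-frequency (not molecular-distance) AMOVA; Φ_ST from
sequence differences and multi-level hierarchies are out of scope.  A
negative variance-component estimate is clipped to 0 in the reported
F_ST — identical populations therefore report exactly 0 — while the raw
value remains available in the returned components (`fst_raw`,
`clip=False`) for users wanting the Arlequin-style negative estimates.

The permutation test shuffles individuals between the two populations
(sizes preserved) and reports p = b/n_perm, the proportion of permuted
**raw** F_ST values at least the observed raw value; using the unclipped
statistic keeps null p-values calibrated (clipping would collapse all
negative nulls onto a point mass).  A `(b+1)/(n_perm+1)` convention is
available by flag.  The default replicate count is 5,040.  Because the
statistic is discrete, tie inclusion makes p-values mildly conservative;
the calibration test bounds this empirically.

The lower-quartile affinity filter selects populations whose F_ST to the
target is at most min + 0.25·(max − min) — a quartile of the *range*, not
of the empirical distribution.  The east/west contrast uses the
Mann–Whitney U test (exact enumeration when n_A+n_B ≤ 12 without ties,
otherwise the normal approximation with tie and continuity corrections),
two-sided by default.

Frequency tables from datasets typed at different resolutions can be
harmonised by an explicit label-collapse mapping, and genetically
homogeneous groups pooled by summing counts.

## Nonmetric MDS

Stress-1 is sqrt(Σ(d̂−d)²/Σd²) over unordered pairs, with disparities d̂
fitted to the configuration distances by pool-adjacent-violators in the
dissimilarity order (primary tie approach: tied dissimilarities are
sub-ordered by current distance and left free).  The configuration is
optimised by SMACOF-style Guttman transforms alternated with the monotone
fit; stress is evaluated every iteration and the loop stops the moment it
fails to decrease, so the reported stress path is non-increasing by
construction.  One start comes from classical (Torgerson) scaling and the
remaining `n_starts−1` (default 20) from seeded Gaussian draws; the lowest
final stress wins.  Defaults: tol 1e-6 on the stress change, max 500
iterations; a run exhausting the budget is flagged unconverged and its
best iterate returned.  Negative F_ST values must be clipped upstream
(dissimilarities are required non-negative); whether published ordinations
clipped or shifted negatives is generally unstated, and clipping was
chosen here.

## Ordinary kriging

Genetic-distance values are interpolated over population coordinates with
ordinary kriging under a linear variogram γ(h) = slope·h (slope 1.0 by
default, configurable) and no nugget, making the interpolator exact at
data points and the Lagrange-constrained weights sum to 1 at every node.
Coordinates are treated as planar decimal degrees — no great-circle
distances — which is adequate at archipelago scale and matches desktop
mapping practice.  The default grid is 100×100 over the data bounding box
padded 5%; output is written as an ESRI ASCII grid plus a flat CSV.
Variogram fitting from empirical semivariance and spherical models are out
of scope.

## Simplex-constrained mixture decomposition

The decomposition minimises ‖Ax − b‖² subject to Σx = 1, x ≥ 0, where the
columns of A are source haplogroup-frequency profiles on the zero-filled
haplogroup union and b is the target profile.  The equality constraint is
enforced by augmenting the system with a heavily weighted sum row solved
with an active-set non-negative least-squares solver, followed by exact
renormalisation; constraint satisfaction is verified to 1e-9 and the KKT
conditions to 1e-7.  Exactly duplicated source columns get the coefficient
mass split equally and the solution flagged degenerate (determinism over
arbitrariness); general rank deficiency is flagged the same way.  The
African reference is pooled by summing constituent counts before frequency
conversion.  The packaged African reference is synthetic (disjoint
haplogroup labels), standing in for reference panels whose frequency
tables are not redistributable here.

Uncertainty comes from a parametric bootstrap: every population's counts
are redrawn multinomially at the observed sample size (target and sources
both, by default; a flag restricts resampling to sources), the profile
matrix rebuilt and the problem re-solved — 5,000 replicates by default,
summarised by median, quartiles and 2.5/97.5 percentiles per source.
Resampling both sides was chosen because the original description of the
resampling is not specific about which profiles were perturbed.  "Drift
dynamics" is approximated by this sampling-variance bootstrap; an explicit
Wright–Fisher pre-smoothing (g rounds of multinomial resampling at size
Ne) exists in the simulator but is off by default since no drift
parameters are published.

## Synthetic data: what it emulates, and what it does not

The generator reconstructs the three study populations from their printed
4-decimal haplogroup frequencies.  mtDNA sample sizes (159, 19, 27) are
published; Y male counts are not, and are recovered as the smallest n
whose rounded counts reproduce every printed frequency exactly (90, 15,
27) — a derivation, not a published fact.  Reconstruction is strict: a
frequency×n product further than 0.5 from an integer, a count failing to
round-trip to the printed precision, or counts not summing to n all raise
errors, so transcription bugs fail loudly.

Simulated Y genotypes are derived along the haplogroup's root path and
ancestral elsewhere, with optional missingness; simulated HVS-I sequences
carry their haplogroup's diagnostic variants plus Poisson-distributed
private substitutions at non-diagnostic positions (a stress-test flag
allows collisions).  Coding-region diagnostics (14022; 1473/3423) travel
in a sidecar genotype table attached to B4a-clade individuals, mirroring
targeted follow-up typing of motif carriers.  Admixed targets draw counts
multinomially from a frequency mixture, optionally after Wright–Fisher
drift.  The pipeline's built-in Malagasy-like target uses mixing
proportions of 0.65 African for the Y and 0.30 African for mtDNA,
reflecting the approximate published contrast between the paternal and
maternal African shares, at target sizes 371 (Y) and 529 (mtDNA).

The fixtures are deliberately idealised: no genotyping error, no
recurrent mutation at diagnostic sites by default, a synthetic reference
window and a synthetic miniature motif table (only the Polynesian- and
Malagasy-motif positions are real diagnostic sites).  Passing the
round-trip suites therefore demonstrates internal correctness of the
estimators and the exactness of the table reconstruction — not robustness
to the noise, homoplasy and database ambiguity of real control-region
data.  Quantities that depend on the full comparative panel (published
ordination stress values, east/west Mann–Whitney p-values, haplotype-
sharing counts against other archipelago populations) cannot be
reproduced from the packaged fixtures; the suites instead verify the
properties of the corresponding estimators, and the fixture-scale
ordination is checked for restart stability.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible
under it.  The test and acceptance workloads were sized for a desk run:
500 random tables for the F_ST oracle equivalence, 1,000 replicates at
5,040 permutations for the calibration check, 5,000-replicate bootstraps
for the recovery checks, and 0.001-step simplex grids for the solver
oracle.
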