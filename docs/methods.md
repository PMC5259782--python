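# Methods

## The problem and the pipeline

Cyanobacterial PEPCs differ by taxonomic order in how strongly metabolites
such as malate, aspartate and fumarate inhibit them. Linking that
order-level phenotype to sequence takes three coordinated analyses: a
residue scan over an aligned protein family stratified by order, a
phylogeny confirming the orders form real clusters, and enzyme kinetics
quantifying the phenotype itself. This package implements all three plus
the synthetic-data generators that give each stage a known ground truth.

## Residue scan

A column is **reference-unique** when the reference sequence carries a
non-gap, non-X residue found in no other sequence at that column. "Every
other sequence" is the strict reading: one matching homolog disqualifies
the column. Under the default `other_gap_policy="mismatch"` a gapped row
counts as differing from the reference (and stays in consensus
denominators); `"ignore"` drops gapped rows, and a column where every
other row is gapped is then not reported, since there is no evidence of
uniqueness.

A column is **clade-discriminating** for a target clade when the clade's
modal residue reaches frequency ≥ θ and differs from each contrast
clade's modal residue (the permissive reading; `strict_contrast=True`
additionally requires the target residue absent from every contrast
member). θ defaults to 0.9 — "highly conserved" is not a number anywhere
in the source analyses, and 0.9 demands near-unanimity in small clades
while tolerating one deviant in clades of ten or more. Modal ties break
toward the alphabetically earlier amino acid, a pure determinism device.
`X` never counts toward a consensus.

The candidate screen is the intersection of the two filters, reported at
reference positions via the coordinate map (1-based on the ungapped
sequence, counting the initiator methionine, so numbers line up with
mutagenesis nomenclature like E954K). Known-site conservation reports
take user-supplied positions because the canonical inhibitor-binding
residues are published as figure annotations, not coordinates.

The aliphatic index defaults to the Ikai weighting
Ai = 100·(X_A + 2.9·X_V + 3.9·(X_I + X_L)); a plain
Ala+Val+Ile+Leu percentage is available via `weighted=False` since the
phrase "ratio of alanine, valine, isoleucine, and leucine" is ambiguous
between the two.

## Phylogeny

Distances are p-distances (mismatches over mutually ungapped compared
columns) or Poisson-corrected −ln(1−p); the correction diverges at p = 1,
which is reported as an error with guidance rather than infinity. Column
selection for tree building defaults to gap-free columns. Tree inference
is Saitou–Nei neighbor joining — an explicit, documented stand-in for
maximum likelihood: the claims tested here are clade monophyly and
bootstrap support, for which NJ on corrected distances suffices and has
the advantage of exactness on additive matrices (verified to 1e-9 against
random generating trees). Negative branch lengths are clamped to zero
with the deficit moved to the sibling edge. Bootstraps resample columns
(not sequences) with replacement, rebuild the tree per replicate, and
annotate each internal bipartition of the point tree with the percentage
of replicates containing it; replicates whose resample makes a pair
incomparable or saturated are skipped and removed from the denominator. A
seed is mandatory. Midpoint rooting is offered for display only.

## Kinetics

Initial rates come from the linear phase of A340 traces: the default
window is the longest prefix keeping r² ≥ 0.99 (minimum 4 points), and
velocity = |slope| / (ε·path) × volume with ε(NADH, 340 nm) =
6.22 mM⁻¹cm⁻¹, 1 cm and 1 mL defaults — the standard coupled-assay
constants. (The source assay's unit definition says NADPH while the assay
mix contains NADH; this package treats that as a typo for NADH.) A rising
trace yields velocity 0 with a warning. Slopes below 1e-12 A/min count as
flat.

Lineweaver–Burk fitting is deliberately the classical procedure:
unweighted ordinary least squares of 1/v on 1/[S], Vmax = 1/intercept,
Km = slope/intercept. Non-positive velocities cannot be
reciprocal-transformed and are dropped with a warning; a non-positive
intercept is reported as a fit failure (this is exactly what an inactive
variant produces). Nonlinear least squares of v = Vmax[S]/(Km+[S]),
initialized from the LB estimate, is the cross-check; the two agree to
1e-6 relative on noiseless data. Replicates are averaged on the velocity
scale before any transformation (switchable to pooling).

One noteworthy negative result from the simulation suite: under the
generator's constant-CV (multiplicative) noise, the double-reciprocal
fit is *not* systematically worse than NLS — both land near 5% median
relative Km error at 5% CV with triplicates, and neither wins a majority
of head-to-head comparisons. The reciprocal transform is pathological
under *additive* noise, where small velocities blow up; constant-CV noise
keeps reciprocal residuals proportionate. NLS remains the preferred
estimator because its superiority does not depend on the noise model, but
passing the recovery tests here says nothing about LB's behaviour on data
with additive error.

Effector analysis is relative activity only: each effector replicate is
divided by the mock mean (×100) and reported as mean ± sample SD with a
paired two-tailed t-test against the mock replicates. Single-point
half-saturating-substrate assays are never converted into Km inferences.
Inhibition modes are labelled from relative Vmax/Km changes beyond a 15%
tolerance: Km↑ alone → competitive-like, Vmax↓ alone →
noncompetitive-like, both↓ → uncompetitive-like, both↑ → the
"Km-and-Vmax-increase (malate/fumarate-type)" signature, neither →
no-effect. Optima are the argmax over the measured grid, no
interpolation; ties resolve to the lower grid value and boundary optima
warn.

## Statistics

Sample (n−1) standard deviations throughout; the SD of one value is an
error, not 0. The paired t-test computes t = d̄/(s_d/√n) with n−1 degrees
of freedom, two-tailed p from the t distribution. Zero-variance
difference vectors — including the exactly-proportional replicates that
noiseless reconstructions produce — raise a degenerate-data error and are
reported as p = None, never p = 0. No multiple-testing correction is
applied. Empirical type-I error at α = 0.05 over 10,000 null triplicate
simulations lands in [0.04, 0.06].

## Synthetic data: what it emulates and what it does not

The MSA generator draws a root sequence, diverges a per-clade profile
(default 0.3 substitution probability per column), copies it to members
with optional within-clade noise, then overwrites planted columns:
unique columns give the reference its residue and everyone else a single
shared residue (the alphabetically earliest non-reference residue, so it
wins consensus ties even in two-member clades); discriminating columns
give each clade its assigned residue and the reference a residue absent
from all clades — making them candidate sites by construction. Optional
indel columns, in which only one non-reference clade has residues, push
reference positions out of register with column indices so coordinate
mapping is genuinely exercised. Substitutions are uniform over the 19
alternatives: conservation patterns are what matter here, not realistic
evolution (no rate matrices, no site-rate heterogeneity, no Γ). Planted
truth is exact for zero within-clade noise, a reference clade of ≥ 2
members, and scans targeting a clade other than the reference's.

The assay generator produces v = fV·Vmax·[S]/(fK·Km+[S])·(1+CV·z) with
multiplicative Gaussian noise — matching the roughly proportional SDs
real effector panels show — and multiplicative, optionally pH-dependent
effector factors. Traces are linear in the initial-rate window by
construction. Activity profiles are Gaussian in pH or temperature. Real
assay data additionally contain substrate depletion curvature, coupled-
enzyme lags, and pipetting error correlated within replicates; none of
these are modelled, so passing the recovery tests demonstrates the
correctness of the estimation machinery, not robustness to every
real-world artifact.

## Problem sizes and acceptance checks

The test suite runs alignments up to ~12×200, trees up to 10 taxa with
500 bootstrap replicates, 200-dataset fitting simulations and a
10,000-iteration t-test null calibration — sizes chosen so the whole
suite completes in seconds while each property still has statistical
teeth. `scripts/acceptance.py` reruns the published-parameter round
trips (wild-type Km 0.34 mM / Vmax 1.74 units/mg on a 6-point titration,
mutant Km 0.82 mM, the second organism's Km 1.1 mM, the 85.2% and 80%
effector reconstructions, and the pH-7.3 optimum) from scratch at run
time.

Three checks from the source study are documented but deliberately not
automated, because they need the original GenBank sequence set, which the
study does not enumerate: the count of 28 reference-unique residues, the
two candidates at reference positions 954/967, and monophyly of the
Chroococcales members. Users with their own full-length PEPC alignment
can run `candidate_screen` and `is_monophyletic` directly to repeat them.

## Known limitations

- No alignment construction: an MSA is an input (or comes from the
  generator).
- No maximum-likelihood or Bayesian phylogenetics, no model selection.
- No Hill/cooperative kinetics, no global multi-substrate fits, no
  progress-curve integration beyond initial rates.
- No entropy- or phylogeny-weighted conservation scores; the scan is the
  two deterministic filters described above.
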