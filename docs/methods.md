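# Methods

This note documents the models, numerical choices and limitations behind
`mecnet`.  Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Electrochemical metrics

The raw signal is a current trace `I(t)` sampled at fixed intervals
(default 30 s).  Total charge is the trapezoidal integral of the raw
samples over a window, with linear interpolation at window boundaries that
fall between samples.  The 5-min rebinned series (non-overlapping groups of
ten samples, bin timestamp at the group midpoint, trailing partial group
averaged as-is so end-of-cycle peaks survive) is used only for peak current
and lag time; the integral deliberately uses the raw samples, since charge
is defined on `I(t)` directly and rebinning would only add discretisation
error.

Coulombic efficiency divides the charge by `F · V · Σ b_s ΔC_s`.  The
electron stoichiometries `b` come from the balanced half-reactions of
complete oxidation to CO₂ (`C_aH_bO_c^q → a CO₂`, electrons
`n = 4a + b − 2c − q`): acetate 8, propionate 14, butyrate 20.  They are
hard-coded but overridable per `SubstrateDelta`, and the convention is that
`ΔC` is the *consumed* concentration, entered as a positive number.  CE is
reported unclipped: a value above 1 signals inconsistent inputs and should
be visible, not hidden.

Lag time is the time (days from trace start) of the first 5-min bin whose
current density exceeds a threshold, default 1 A/m².  A trace that never
crosses returns `None` rather than a sentinel number.

On synthetic traces the 30-s trapezoid agrees with a 100×-finer reference
grid to well under 0.1 %, so a prescribed CE is recovered within the 0.5 %
tolerance the acceptance test demands.

## Synthetic current traces

The generator is a caricature of MEC startup dynamics, not a biofilm
model: zero current (plus Gaussian noise) during a lag phase, then batch
cycles every `feed_interval_days`.  Within a cycle the signal steps to 80 %
of its envelope on feeding (real traces rise sharply when substrate
arrives), relaxes to 100 % with a short time constant, and decays
exponentially once electron donors are depleted at 70 % of the cycle.  The
envelope rises logistically from half the plateau density at the end of the
lag to the plateau at `peak_day`, then declines linearly by
`decline_fraction` at the end of the run.  The half-plateau start is what
guarantees that, at the default plateau of 3 A/m², the first 5-min bin
after the lag already exceeds the 1 A/m² lag threshold — so the lag
parameter is recovered to within one bin by construction.

Defaults mirror the study conditions: 30-s sampling, ~100-day runs, 70-ml
liquid volume, feeding every 2.5 days, lag of 10 days (observed range
5–17 d), peak near day 30, plateau ~3 A/m², and a modest post-peak decline.
The anode area is not printed in the source material; 10 cm² of projected
carbon cloth is assumed so that densities land on the observed scale.  The
deterministic density profile is exposed (`current_density_profile`) so
tests can build independent fine-grid references.

## Synthetic communities

Count tables come from a logistic-normal → multinomial model: per-sample
log abundances are `N(base, Σ)`, softmax-transformed and sampled as
`Multinomial(library_size)`.  This preserves the compositional structure
SparCC assumes.  The base log-abundance ladder spans ~4 natural-log units
(a few dominant taxa, many rare), library size defaults to 20 000 reads and
n = 60 samples — a scale at which correlation recovery is demanding but
feasible.  Associations are planted as off-diagonal entries of Σ via
`planted_covariance`, which requires disjoint pairs so the matrix stays
positive semi-definite for any |ρ| ≤ 1.  Optional habitat labels add a mean
shift to a habitat-specific block of taxa, mimicking location-driven
dominance (anode vs. cathode vs. suspension).

Trees are built by random sequential joining with branch lengths
`0.01 + Exp(0.05)`, so unrelated tips are ≥ 0.02 apart; designated
near-identical pairs are joined first as cherries at a prescribed tiny
tip-to-tip distance (default 0.002).  One master seed spawns independent
substreams for counts and tree.

What the generator does *not* emulate: sequencing error and chimeras,
overdispersion beyond the logistic-normal, rarefaction-depth variation,
taxonomic structure, or any mechanistic link between community and current.
Passing tests therefore demonstrate correctness of the *algorithms* under a
plausible generative model, not performance on real amplicon data.

## Hill diversity and dissimilarity

Hill numbers use the standard closed forms with zero-abundance terms
excluded; `q = 1` is evaluated as `exp(Shannon)` and tested to be the
numerical limit of the neighbouring orders.  Pairwise beta diversity uses
the equal-weight multiplicative decomposition: gamma is the Hill number of
the pooled mean composition, alpha is the two-sample Hill mean
(`[Σ_ij (p_ij/2)^q]^{1/(1−q)}/2`, with the exponential form at q = 1), and
the reported index is the local dissimilarity `(β − 1)/(N − 1)`, which is 0
for identical compositions and 1 for disjoint ones.  Values are clamped to
[0, 1] against floating-point spill.

## Raup–Crick null model

For each sample pair the observed dissimilarity at order `q` is ranked
within a null ensemble (default 999 iterations; ties counted at half
weight, which keeps qRC unbiased under the null).  Each null community
preserves the sample's observed richness and read depth.  Taxa are drawn
without replacement with probability proportional to their occupancy
frequency across the table; every selected taxon receives one read and the
remainder are multinomial with probabilities proportional to metacommunity
mean relative abundances.  Occupancy and abundance weights can also be
passed explicitly — this is how the calibration study evaluates independent
two-sample tables against the exact generating null rather than weights
re-estimated from two samples.  Taxa absent from the table get a tiny
weight floor so richness remains satisfiable.

Null realisations are generated once per sample and shared across pairs,
which keeps the cost at `O(n_samples · iterations)` assemblies.  The
self-calibration study (acceptance) generates 200 independent pairs from
the null process and checks that qRC is indistinguishable from uniform
(KS p > 0.01) at 199 iterations.

## Mantel test

Pearson correlation of the off-diagonal upper triangles, with significance
from jointly permuting rows and columns of the second matrix and the
two-sided add-one rule `p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + permutations)`.
Implemented in-package for seedable determinism; the statistic is
cross-checked against scikit-bio's implementation in the test suite.

## ASV filtering and phylogenetic merging

The filter keeps an ASV iff it is non-zero in ≥ 2 samples *and* exceeds
0.1 % relative abundance in ≥ 1 sample (both configurable); it is
idempotent and never touches the sample set.  Merging collapses
single-linkage clusters of tips at cophenetic distance ≤ ε — equivalently
connected components of the ≤ ε graph — summing counts and labelling the
merged taxon by its most abundant member.  Per-sample read totals are
invariant under merging.  The default ε = 0.004 branch-length units
corresponds to roughly one substitution across a 253-bp 16S V4 amplicon,
the situation where two ASVs are plausibly one organism; it is a
configurable default, not a universal constant.  Cophenetic distances are
computed with dendropy and verified against a graph shortest-path oracle.

## SparCC

Implemented from the log-ratio variance formulation.  Per resample, taxon
fractions are drawn from a `Dirichlet(counts + 1)` posterior per sample
(this regularises zeros); the variation matrix is
`t_ij = var(log x_i − log x_j) = v_i + v_j − 2 cov_ij`, computed from one
covariance of the log fractions.  Under the sparsity assumption the basis
variances `w` solve the linear system `(diag(d) + A) w = t·A`, where `A`
marks included pairs and `d` the per-taxon inclusion counts; correlations
are `ρ_ij = (w_i + w_j − t_ij)/(2√(w_i w_j))`, clipped to [−1, 1].  The
strongest pair above the exclusion threshold (default 0.1) is removed and
the system re-solved, up to 10 iterations, never stripping a taxon below
three partners (the system would degenerate).  The final matrix is the
elementwise median over 20 resamples, symmetrised with unit diagonal.
Basis variances are floored at 1e−12 before the square root.

P-values come from a permutation null: each ASV column is permuted
independently (destroying associations, preserving marginals), SparCC is
recomputed, and `p = (1 + #{|r_null| ≥ |r_obs|})/(1 + n_bootstraps)` — so p
is never exactly 0 and the minimum attainable value is `1/(1+B)`.

Calibration at n = 500 samples and 30 taxa: independent components give a
maximum off-diagonal |r| well below 0.3, and a planted basis correlation of
0.8 is recovered within ±0.15 (both recomputed by the acceptance script).

## Edge validation and network statistics

An edge requires |Spearman ρ| > 0.6 *and* |SparCC r| > 0.6, both p < 0.05,
and concordant signs; the stricter both-p reading was chosen deliberately,
and sign conflicts invalidate the edge because no sign could be defended.
The edge weight and sign come from SparCC.  No multiple-testing correction
is applied by default, matching common practice for this dual-criterion
design; isolated nodes are dropped before summary statistics, so node
counts reflect the connected taxa.

Summary statistics: signed edge counts and percentages (computed from
counts, so they sum to exactly 100), edge density `2E/(N(N−1))`, module
count and modularity from greedy (Clauset–Newman–Moore) modularity
maximisation on the unsigned graph, and the mean local clustering
coefficient.  Louvain and transitivity are selectable alternatives; which
algorithm a published table used is usually unstated, so module counts and
modularity are not promised to match any particular report.

## Problem sizes and determinism

The acceptance studies use: 60-day traces at 30-s sampling for the
electrochemical metrics; 200 independent pairs × 199 iterations for
Raup–Crick calibration; n = 500 samples × 30 taxa for the SparCC null and
recovery studies; and four repetitions of the n = 60 pipeline study with
four planted pairs at |ρ| = 0.8 (16 planted edges total).  These sizes give
stable statistics while keeping a full run in well under a minute.  Every
stochastic component accepts a seed; the CLI and acceptance script derive
per-stage substreams from one master seed via `numpy.random.SeedSequence`,
so identical seeds give byte-identical outputs.

## Known limitations

* The trace envelope is qualitative; it is never fit to measured data, and
  parameters such as `peak_day` are descriptive inputs, not estimates.
* The Raup–Crick assembly weighting (occupancy selection, mean-abundance
  read allocation) is one defensible choice among several; it is validated
  by self-calibration, not by agreement with any external implementation.
* SparCC assumes a sparse true correlation network; dense strong
  correlation structure violates the basis approximation and biases
  estimates.
* The dissimilarity index is the local overlap-type measure
  `(β − 1)/(N − 1)` at every order, including q = 1; other transforms of β
  exist and would give different absolute values.
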