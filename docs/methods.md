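# Methods

## Model

The package models a genes × samples expression matrix as a set of
trajectories along the **expression index** (EI), `E_i = Σ_j M_ji`, the
summed expression of a sample.  Samples ordered by ascending EI form a
pseudo-continuous axis; ties are broken by original column order and,
for the fitted axis, separated by a deterministic jitter of
`1e-9 · span · rank` so the axis is strictly increasing.

Each target gene *j* is decomposed additively,

    y_j(E_i) = a_j(E_i) + Σ_{j' ∈ R(j)} G_{j|j'}(M_{j'}(E_i)) + e_j(E_i),

with `a_j` the independent (endogenous) expression curve — a B-spline
over EI — and `G_{j|j'}` the dependent component contributed by
regulator *j′*, a B-spline function of the regulator's expression.
Differentiating along EI recovers the quasi-dynamic ODE view
`dM_j/dE = g_j + Σ g_{j|j'}` with `g = dG/dE`.  All components are
normalized to zero at the first (lowest-EI) sample, so the network built
at `E_1` has no edges and every edge weight reads as "dependent amount
gained since `E_1`".

An earlier implementation followed a stricter collocation scheme in
which the dependent terms were cumulative EI-integrals of spline rates
evaluated on smoothed regulator curves.  That scheme is not usable in
practice: the integrated columns of different regulators are
near-collinear smooth ramps, and on data generated from the collocation
model class itself edge recovery stayed at chance.  The observation-form
decomposition above keeps the same semantics (signed, weighted,
EI-varying dependent amounts; rates by differentiation; perturbation
integrals as exact differences) while making regulators statistically
distinguishable.

## Fitting

**Stage 1 — regulator selection.**  For each target the incoming links
are chosen by a penalized weighted least-squares criterion: the
target's own EI-basis is unpenalized, each candidate regulator
contributes one group of spline coefficients (its basis evaluated at
the regulator's observed expression, centered at the first sample), and
the group-LASSO penalty `λ Σ w_g ‖β_g‖₂` shrinks whole groups exactly to
zero.  The observation weights are the boundary-vanishing parabolic bump
`z(E) = (E − E_1)(E_N − E)`, scaled to maximum 1 (non-negative and zero
at both ends).  The penalty is chosen over a geometric grid of 10 values
from `λ_max` down to `λ_max/100` by BIC, or extended BIC
(`+ 2γ·k·log(m−1)` for k selected groups) when `criterion="ebic"`; an
adaptive variant reweights groups by the inverse norms of an
unpenalized fit.  The number of selected regulators is capped at
(candidates − 1): besides encoding the sparsity premise `d_j ≪ m`, the
cap excludes the one exactly degenerate solution that exists whenever
the EI equals the sum of the modeled genes (each gene is then an exact
linear combination of EI and all other genes).

The solver is a hand-written block coordinate descent with *exact*
group updates: the zero test is the group subgradient condition and the
non-zero update solves the secular equation in the group's eigenbasis
by a guarded Newton iteration.  Before descent, the unpenalized block
is profiled out of the response and of every group (an equivalent
reformulation that removes the shared smooth trend and speeds up
convergence dramatically).  At `λ = 0` the criterion minimizer is the
weighted least-squares solution and is computed directly.

**Stage 2 — likelihood refit.**  On the selected support each target is
refit by ordinary least squares; with Gaussian errors this is the
maximum-likelihood estimate, `σ̂_j² = RSS/N`, and the per-target
log-likelihoods sum to the system log-likelihood.  Residual
cross-covariances `σ_{jj'}` are estimated post hoc from the residual
matrix.  When sample metadata provides subject and time labels and
`cov="ar1_time"`, the lag-1 correlation of within-subject residuals
across consecutive time points is estimated as the AR(1) parameter ρ;
otherwise residuals are treated as independent across samples.

**Basis defaults.**  Independent curves: cubic B-splines with interior
knots at EI quantiles; `n_interior` defaults to 0 and `"auto"` chooses
per target from {0,1,2,3} by BIC of the independent-only fit.
Dependent groups: degree 1 with no interior knots (effectively linear
in regulator expression) by default.  The low default order is a
deliberate bias–variance choice: flexible (cubic) dependent groups
absorb smooth-shape variance indiscriminately, so false regulators fit
as well as true ones; keeping the dependency terms low-complexity while
the independent curve stays flexible is what makes incoming links
identifiable.  Both orders are per-gene configurable.

## Networks

A network at EI value *e* has node sizes `G_j(e) = a_j(e) − a_j(E_1)`
and directed edges `j' → j` weighted by `G_{j|j'}(e)` (positive =
promotion, red; negative = inhibition, blue; `|w| < 1e-10` counts as no
link).  Dependent amounts are exact at the sample EIs and linearly
interpolated in between, so a personalized network for any sample is
the network at that sample's EI, and interpolated or extrapolated EIs
are supported (extrapolation behind a flag).  The perturbed network
between `e1 < e2` carries `Δ_{j|j'} = G_{j|j'}(e2) − G_{j|j'}(e1)`,
which is exactly additive over adjacent intervals.  Group averages are
arithmetic means of each subject's personalized network evaluated at
its own EI (a common-EI mode is available).

Interaction taxonomy on the ordered weight pair (j'→j, j→j'): (+,+)
synergism; (−,−) antagonism; (+,0)/(0,+) directional synergism;
(−,0)/(0,−) directional antagonism; (−,+) synergistic repression by the
inhibitor; (+,−) antagonistic altruism by the promoter; (0,0) neutral.
Node labels, which may co-occur: *social* (more outgoing than incoming
links), *core* (more outgoing links than the per-node average of total
links), *solitary* (fewer total links than that average), *hub* (total
connectivity strictly above the average).

## Significance test

The full sparse system is tested against the reduced system in which
every gene evolves independently; the statistic is
`LR = 2(ℓ_full − ℓ_null) ≥ 0` (the models are nested and share the
fitting procedure).  The null distribution is obtained by permutation:
each gene's profile is shuffled across samples independently, the whole
pipeline — EI handling, regulator selection, refit — is re-run on the
shuffled data, and the threshold is the 95th percentile of the
permutation LRs (1000 permutations by default).  The reported decision
uses the exact permutation p-value `(1 + #{LR_null ≥ LR_obs})/(1 + B)`
rather than a bare threshold comparison: the null LR distribution has
an atom at zero (permutations in which nothing is selected), and with
such ties "observed above the 95th percentile" alone over-rejects,
whereas the tie-respecting p-value is exactly calibrated under
exchangeability (measured type-I error 5% at the nominal 5%).  A
caller-supplied EI
axis stays fixed under permutation; an EI computed from the data is
recomputed from each shuffled matrix.  Shuffling whole profiles *among
gene labels*, which would preserve each profile's shape exactly, is
degenerate for a system-wide statistic — the total LR is a sum of
per-target terms over the same profile set and is invariant under
relabeling — hence the per-gene shuffle, which is exchangeable under
the independence null.  Permutation seeds are spawned up front from the
root seed, so results are independent of execution order and
parallelism.

## Functional clustering

Modules are found with a finite mixture over gene trajectories: module
k claims mean curve `α_k E^{β_k}` (the same allometric family the
screening stage fits) with module-specific Gaussian residual variance.
EM alternates posterior responsibilities with weighted power-curve
refits (Levenberg–Marquardt on the responsibility-weighted mean
profile); 10 seeded restarts by default, convergence at relative
log-likelihood change < 1e-6, empty modules trigger a reseeded restart.
The module count minimizes `AIC = −2ℓ + 2(3K + K − 1)`.  Aggregation
is the member mean by default (keeps modules on a comparable scale);
the sum option conserves the EI exactly for workflows that recompute EI
after aggregation.  The mixture is a stand-in for the cited
functional-clustering family, not a re-implementation of it.

## Synthetic data

The generator emulates the benchmark design.  Each gene carries a
latent trajectory `x_j(E) = α_j E^{β_j} + η_j(E)`: an allometric mean
curve (α ~ U(0.5, 2), β ~ U(−0.8, 0.8)) plus an intrinsic AR(1)
fluctuation (sd 0.3, lag correlation 0.5) representing biological
variability around the scaling law.  A sparse signed coupling matrix W
(3 regulators per gene, weights ±0.7, drawn acyclically so the coupled
system is stable and the direction of influence is well defined) acts
recursively on means, `μ = (I − W)^{-1} x`, and AR(1) measurement noise
at the scenario's variance/correlation is added:
`y = μ + ε`.  Scenario conditions follow the benchmark: N ∈ {50, 100,
200} crossed with (variance, correlation) ∈ {0.1, 1.0} × {0.3, 0.0} —
12 scenarios; m = 20 genes by default.  Everything is reproducible from
a single seed, and an explicit adjacency can be supplied for planted
single-edge experiments.

What the generator does *not* emulate: count noise and
mean–variance coupling of sequencing data, batch effects, unequal EI
spacing, and feedback through the EI itself (the EI grid is a fixed
design axis rather than the column sums of the generated matrix, which
lets the planted couplings be defined independently of the closure
constraint).  Passing tests on this generator therefore demonstrate the
machinery's correctness and its behavior under the stated noise
conditions, not performance on real sequencing data.

Edge recovery is scored over all m(m−1) ordered pairs: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), positive likelihood ratio
sensitivity/(1−specificity) (+∞ flagged when specificity is 1), and
AUC from scoring each candidate edge by the penalty at which its group
enters the solution path.  A gene-level (direction-collapsed) mode is
available.  The evaluation harness selects with extended BIC (γ = 1.0)
over 8 penalty values — the multiplicity-guarding member of the
criterion family — while the package-level default remains plain BIC.

## Known limitations

* **Direction of influence.**  At steady state an influence that
  propagates fluctuations makes the child a genuine statistical
  predictor of its parent, so reversed and indirect edges carry real
  signal that no information criterion can fully reject.  Directed
  specificity consequently degrades as the sample size grows in the
  high-signal scenarios (≈ 0.80 at N = 200, variance 0.1) while
  sensitivity rises; at N = 50 specificity is ≈ 0.95+.  The qualitative
  structure of the benchmark grid (sensitivity rising with N, falling
  with noise variance) is reproduced; its absolute specificity level is
  not reachable at high sensitivity in this regression-based setting.
* **Dependent-curve attribution.**  Recovered dependent amounts carry
  the regulator's measurement noise and an errors-in-variables
  attenuation; on planted single-edge systems with noise sd 0.1 the
  relative L2 error of the recovered curve is ≈ 20% even though the
  true regulator is found in 100% of replicates.
* The mixture used for module discovery assumes power-law mean curves;
  genes with non-monotone EI profiles are forced into the nearest
  monotone module.
* The EI is a proxy axis, not time; rates "per EI" are comparable
  across genes but not convertible to rates per hour.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run reduced Monte-Carlo
sizes chosen as the package's own desk-scale defaults: the scenario
grid at 5–6 replicates per scenario, type-I error with 50–100 null
systems of m = 4, N = 40 (permutation size 100–200), structure recovery
with 25–30 replicates of the m = 5, N = 200 planted system, and power
of the permutation test over 10 planted systems.  Full-scale settings
(50 replicates, 1000 permutations) are available through the same
functions.
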