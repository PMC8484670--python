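# Methods

## The model

`tamodel` describes the expression dynamics of a bacterial type II
toxin–antitoxin (TA) operon with three coupled ODEs for the antitoxin
(z1), the toxin (z2) and the neutralising TA complex (z3):

    dz1/dt = −d1 z1 + k1 / ((1 + z3/s1)(bm z2 + 1)) − k2 z1 z2 + z3
    dz2/dt = −d2 z2 / (bc z2 + 1) − k2 z1 z2 + z3
             + 1 / ((1 + z3/s2)(bm z2 + 1))
    dz3/dt = −d3 (−k2 z1 z2 + z3)

The mechanism encoded is minimal: mass-action complex formation
(k2 z1 z2) and dissociation (z3, released back into both free pools);
transcriptional repression of both genes by the complex (the 1/(1 + z3/s)
factors, with separate scales s1 and s2 for the antitoxin and toxin
promoters); and growth modulation by free toxin — toxin slows growth,
which both lowers all protein production (the 1/(bm z2 + 1) factor) and
reduces dilution of the toxin itself (the (bc z2 + 1) divisor on its
decay).  Conditional cooperativity, coupling between TA modules and
stochastic (single-cell) effects are deliberately out of scope: the data
this model targets are bulk expression time courses on a timescale of
hours.

This system is a rescaled form of a dimensional model in physical
concentrations (y1, y2, y3) whose toxin production rate k2′ is absorbed
into the units: y1 = k2′ z1, y2 = k2′ z2, y3 = (k2′/d3) z3, with
k1 = k1′/k2′, k2 = k2′ k3, s1 = d3 s1′/k2′, s2 = d3 s2′/k2′, bm = bm′ k2′,
bc = bc′ k2′.  Both forms are implemented (`z_rhs`, `original_rhs`) and the
equivalence is tested by integrating both systems and mapping one onto the
other; the dimensional form is practically unidentifiable from ~10
timepoints, which is why fitting always happens in the rescaled form.
The rescaled model has 10 adjustable constants: the nine kinetic constants
above plus the unobserved initial complex level c0 = z3(0).

Initial conditions default to z1(0) = z2(0) = 0 with z3(0) = c0 fitted
(the pre-induction assumption); starting from the earliest observed
values or from each curve's mean are available as alternative modes, with
c0 fitted in every mode.

### Parameters, units, defaults

| name | meaning | units |
|------|---------|-------|
| k1 | antitoxin/toxin maximal production ratio | – |
| k2 | effective complex association rate | 1/(conc·h) |
| d1, d2 | antitoxin / toxin decay (degradation + dilution) | 1/h |
| d3 | complex turnover rate | 1/h |
| s1, s2 | complex repression scales (antitoxin / toxin promoter) | conc |
| bm | toxin inhibition of protein production | 1/conc |
| bc | toxin inhibition of its own dilution | 1/conc |
| c0 | initial complex level z3(0) | conc |

Time is in hours throughout; time grids are caller-supplied and never
resampled.  Observed values are raw expression multiplied by a constant
c = 1e5 so that fitted numbers are O(1)–O(100) and round-off in the
optimiser is harmless.

### Numerical integration

LSODA (adaptive, stiffness-switching; the system turns mildly stiff for
large d3 or strongly displaced rate constants) with rtol 1e-8 / atol 1e-10
for reporting-quality trajectories and a looser 1e-6 / 1e-8 inside fitting
loops.  The repression factors are evaluated as s/(s + z3) — algebraically
identical for s > 0 but immune to overflow when z3/s is huge.  There is no
clipping: non-negativity is preserved by tolerance choice and excursions
beyond −10·atol (relative to the trajectory amplitude) raise an error.
Integrator failures inside the objective return a large finite penalty
(1e12) so simplex search can retreat.

## The nested model family

Seven constrained variants are obtained from the full model by tying
s1 = s2 and/or fixing bm = 0, bc = 0 (and, in the simplest variant,
s1 = s2 = 1).  Free-parameter counts: full 10; s1=s2 9; s1=s2_no_bm 8;
s1=s2_no_bc 8; s1=s2_no_bm_bc 7; s1!=s2_no_bm 9; s1!=s2_no_bc 9;
no_s1_s2_bm_bc 6.  Every variant's free-parameter order is fixed and
serialised with results so parameter vectors are comparable across runs.

## Objective and fitting protocol

Both observed curves of a pair are fitted simultaneously with a
mean-weighted sum of squared residuals: each curve's residuals carry
weight 1/mean(curve)², making its contribution relative to its own scale —
otherwise the lower-abundance curve (often the toxin) would be ignored.
The weight exponent is a design choice of this package; it follows
directly from the requirement that a joint rescaling of a curve and its
prediction leaves that curve's contribution unchanged.

Optimisation runs in transformed coordinates: log10 for the strictly
positive constants inside a [−4, 4] box (kinetic constants in biological
systems spread over orders of magnitude), linear in [0, 1e4] for bm, bc,
c0; the box is enforced by clipping in the decode step.  The search is
basin-hopping (default 50 hops, step 0.5 log-units) over a composite local
minimiser: Nelder–Mead (default cap 2000 iterations) followed by a
trust-region least-squares polish of the weighted residual vector
(finite-difference step 1e-4, well above the integrator tolerance, so the
numerical Jacobian is smooth).  The simplex handles the rugged
large-scale landscape; the least-squares step pulls smooth basins down to
the solver-tolerance floor that the simplex alone reaches only with a far
larger budget.  Start points are drawn uniformly from a moderate region
(log10 in [−1.5, 1.5]; [0, 3] for the linear parameters) rather than the
full box: dynamics on an hours timescale live within a few decades of 1,
and basin-hopping explores outward from there.  The contract is a
deterministic (per seed) *local* minimum; globality is never claimed.

`fit_all` fits every (pair, variant) combination with sub-seeds derived
deterministically from (master seed, pair, variant), so results are
independent of iteration or scheduling order.  Two deterministic
optimum-sharing refinements follow:

* **Cross-pair warm starts** — each pair is re-polished (least squares
  only) from the best few optima found on other pairs for the same
  variant.  Pairs governed by a shared mechanism sit in nearby parameter
  basins, so a basin found on one pair is an excellent start for its
  neighbours; this removes most spurious local-minimum scatter from the
  per-pair parameter vectors.
* **Nesting polish** — the full model is re-polished from each constrained
  variant's optimum on the same pair.  Every constrained optimum is a
  feasible full-model point, so this can only lower the full model's chi2
  and makes the expected nesting inequality (full ≤ each variant) hold in
  practice rather than merely in expectation.

## Model selection

For least-squares fits, aic = N ln(chi2/N) + 2 Nv and
bic = N ln(chi2/N) + ln(N) Nv.  The collective comparison sums chi2 over
all pairs and counts N as the total number of timepoints (a pair's
timepoint count enters once, not once per curve: 11 pairs × 10 timepoints
give N = 110); a `count_curves_separately` switch exists for sensitivity
analysis.  Nv is the per-model adjustable-parameter count (10 for the full
model), not the total over independent per-pair fits — the criteria are
used to rank model *structures*, and both conventions shift all rows by a
pair-count factor without changing the chi2 term.  A fit that is
numerically zero is floored at 1e-12 with a warning before taking the
logarithm.  Ties in `best_model` break toward fewer parameters, then
lexicographic name.

## Clustering of fitted parameter vectors

Each pair's fitted full-model parameter vector (10 constants) is a feature
vector.  Default preprocessing is log10 on strictly positive columns
(zeros in non-negative columns are offset by 1e-3 × the column's smallest
positive value) followed by per-column standardisation (zero mean, unit
population variance) — kinetic constants spread over decades, and a
Euclidean eps is only meaningful on a normalised scale.  PCA (components'
signs fixed so each axis's largest-magnitude loading is positive) embeds
the pairs in 2-D; DBSCAN with eps = 0.8 and min_samples = 3 (min_samples
must be ≤ the expected main-cluster size to make it discoverable among 11
points) separates a dense central cluster from noise points reported as
outliers.  Clustering the full 10-D standardized matrix instead of the
2-D scores is supported.  Border points reachable from two clusters go to
the cluster discovered first in deterministic row order (scikit-learn's
convention).

## Synthetic data generator

The generator emulates the shape of the targeted experimental data: 11
pairs × 10 timepoints over 0–10 h, two curves per pair, values on the
c = 1e5 scale.  Central-region defaults (log-uniform draws for positive
constants, uniform for bm, bc, c0) keep rates on the hours timescale with
a toxin markedly more stable than the antitoxin (d2 ∈ [0.2, 0.5]/h vs
d1 ∈ [1, 3]/h), strong complex repression of the antitoxin promoter
(s1 ∈ [0.05, 0.2]) versus a weaker toxin-promoter scale (s2 ∈ [1, 3]), and
active growth feedbacks (bm, bc ∈ [0.5, 2]).  These ranges were chosen so
that every ingredient of the full model genuinely shapes the curves — z3
crosses the s1/s2 scales and z2 reaches the 1/bm, 1/bc scale during the
time course — which makes the model practically identifiable from
noiseless data and gives the constrained variants a real structural
deficit to be penalised for.

Outlier pairs take a central draw and displace a random subset (default 3)
of the strictly positive constants by a fixed number of decades (default
2) in random directions, a different direction per pair, so outliers are
far from the central region *and* from each other.  The planted
central/outlier partition is a construction for testing the pipeline; it
is not a claim about why real TA pairs separate.

Observation noise is multiplicative lognormal (i.i.d. per point; additive
Gaussian available), the standard stand-in for expression measurement
noise; the default is noiseless because the benchmark suites measure
method behaviour, not robustness.  What passing these suites shows is that
the pipeline recovers structure *its own model generated* under realistic
shapes and scales; it does not show that real RNA-Seq noise, library-size
effects or model misspecification are handled — the generator does not
model counts, replicates or any mRNA/protein distinction.

## Benchmark sizes and reproducibility

The acceptance-grade benchmark fits 11 pairs × 8 variants with a reduced
budget (10 hops, Nelder–Mead capped at 150 iterations, least-squares
polish capped at 100 iterations) — the package's chosen desk-scale
configuration, roughly a quarter-hour on one CPU; the protocol and
defaults scale up unchanged.  Everything is deterministic given the master
seed: generator draws, optimiser starts, hop proposals and sub-seeds
derived per (pair, variant).  `scripts/acceptance.py --seed N --out f.json`
re-runs the entire analysis from scratch and writes the headline numbers.

## Known limitations

* Local optimisation only; with very low budgets individual pairs can
  stall in poor basins (the warm-start sharing mitigates but does not
  eliminate this, especially for strongly displaced outlier pairs).
* Parameter vectors are only as comparable as the fits are converged;
  trajectory agreement does not imply parameter agreement when a
  saturation scale is not excited by the data.
* No uncertainty quantification (covariances/standard errors of fitted
  parameters) and no formal identifiability analysis.
* The information criteria assume i.i.d. Gaussian residuals after
  weighting; expression noise is at best approximately so.
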