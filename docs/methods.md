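# Methods

## Problem and model

`ljsurrogate` fits Lennard-Jones (LJ) nonbonded parameters of a small-molecule
force field against experimental condensed-phase properties. The optimization
variable is a vector θ of per-SMIRKS-type parameters — a well depth ε
(kcal/mol) and a well-position parameter R_min/2 (Å) for each refitted type;
the bundled default space covers six types (hydrogen on tetravalent carbon,
generic carbon, tetravalent carbon, generic oxygen, ether-type oxygen,
hydroxyl-type oxygen), twelve parameters in all. SMIRKS strings are opaque
labels here: no pattern matching against molecules is performed.

The fitness of θ is a scaled least-squares objective over N property types,
each with M_n measurements:

    χ(θ) = (1/N) Σ_n (1/M_n) Σ_m ((y_m(θ) − y_m) / d_n)²

a ForceBalance-style form with the regularization (prior) term deliberately
omitted so the search is unconstrained by the starting point. The scaling
coefficients d_n are set once, to the root-mean-square deviation of the
*baseline* force field's predictions per property type, and frozen for the
run. With the (1/N)(1/M_n) normalization this makes every property type
contribute exactly 1/N at the baseline, so χ(baseline) = 1 is an exact anchor
— the test suite asserts it to 1e-12. The absolute χ scale is therefore a
convention: only ratios to the baseline are meaningful. Predicted
uncertainties are carried in records but not propagated into χ (point
estimates only).

## The multi-fidelity loop

Evaluating χ exactly ("simulation level") costs one molecular-dynamics
property estimation per measurement; the loop spends those evaluations
sparingly and does the actual searching on cheap Gaussian-process surrogates:

1. Simulate an initial sample of n_initial vectors — the baseline plus an
   (n_initial − 1)-point Latin hypercube design over the initial box (per-key
   percentage ranges of the baseline, e.g. (95, 105)%; the hydrogen ε range
   is (50, 150)%). The LHS is plain randomized stratification (one uniform
   draw per stratum, independent permutations across dimensions), seeded.
2. Calibrate d_n on the baseline record; fit one GP per measurement from all
   usable simulations; set the search box per key to
   [min(pool)/η, max(pool)·η] with η = 1.1; minimize the surrogate-level χ
   with differential evolution.
3. Evaluate the proposal at simulation level. Accept iff its simulation χ
   beats the incumbent (the best accepted vector so far, starting at the
   baseline); accepted objectives are therefore strictly decreasing.
4. Add the new simulation to the pool regardless of acceptance and rebuild
   the surrogates; the bounds are recomputed from the enlarged pool each
   iteration and can only grow.
5. If the surrogate search cannot beat the incumbent, rebuild with a
   length-scale floor (loose, l > 1e-10; then strict, l > 1e-5) and terminate
   if the strict level still cannot improve. As a configurable guard
   (`escalate_on_repeated_rejection`, on by default) two consecutive
   simulation-level rejections at the same constraint level also escalate.
6. Stop at `max_iterations`, or at an optional χ target.

A run's simulation budget is exactly n_initial + (simulated iterations).

Records are excluded from surrogate building when the evaluation failed or
when any predicted density falls *strictly* below 20% of experiment (a likely
phase change; the boundary value is retained). A failed baseline evaluation
is fatal because d_n cannot be calibrated.

## Surrogates

One GP per measurement (never a GP of χ itself), constant mean, anisotropic
RBF kernel with one length scale per parameter (ARD). Hyperparameters
maximize the marginal likelihood by multi-restart L-BFGS (default 5 restarts,
seeded; replicate-scale runs in the tests and the acceptance script use 2).
A homoscedastic noise variance is inferred with a jitter floor of 1e-8 by
default, or pinned when the evaluator is noise-free; ill-conditioned systems
escalate the jitter a few steps before raising. Predictions are the posterior
mean only — the surrogate carries no statistical uncertainty into χ.

Inputs and outputs are used in raw units by default (so length scales are in
kcal/mol or Å); min-max input and standardizing output normalization exists
behind an opt-in flag. Length-scale constraint levels impose their floor as a
hard optimizer bound placed infinitesimally above the stated threshold, so
"all fitted l strictly exceed the bound" holds exactly.

## Global and local search

Differential evolution uses SciPy's implementation and defaults: population
multiplier 15 per dimension (180 vectors for 12 parameters), dithered
mutation in (0.5, 1), recombination 0.7, relative convergence tolerance 0.01,
seeded, with a final L-BFGS-B polish of the best member (on by default).
Surrogate χ is evaluated vectorized across each generation. Local
minimization (for the polish and for robustness diagnostics) is
bound-constrained L-BFGS-B with finite-difference gradients; if descent fails
to improve on the start, the start is returned.

## Synthetic ground truth

The bundled evaluator replaces molecular dynamics with a planted-optimum
response surface so the whole method is exercisable at desk scale:

    y_m(θ) = y_m · (1 + Σ_{i∈dep(m)} a_{m,i} s_i² + Σ b s_i s_j + ripple) + ε,
    s_i = (θ_i − θ*_i)/θ*_i

with θ* drawn uniformly inside the initial sampling box. Fractional
parameterization keeps curvatures unitless and comparable across ε and
R_min/2. Design choices:

- **Segmented dependencies.** Hydrogen and tetravalent-carbon keys are
  exercised by every compound; generic C/O keys only by carbonyl-bearing
  groups (esters, ketones); ether and hydroxyl oxygens only by their groups.
  Mixture measurements union their two components' key sets.
- **Curvature magnitudes.** Densities load mainly on R_min/2 curvature
  (weight 8) and enthalpies mainly on ε curvature (weight 9), with weak
  cross-loadings (0.5 and 2), each scattered by a uniform (0.5, 1.5) factor.
  Keys whose initial range half-width exceeds 10% are attenuated by
  0.1/half-width so the wide hydrogen-ε range keeps a physical response.
  These magnitudes were chosen so the baseline's deviations resemble a
  typical starting force field: ~2–3% relative in density and ~20% in
  enthalpy of vaporization.
- **Noise.** Additive Gaussian, per property type, defaults 0.003 g/mL for
  densities and 0.3 kJ/mol for enthalpies — the order of typical simulation
  statistical uncertainties. Noise is a deterministic function of (θ, spec
  seed), so the evaluator contract (same vector → same record) holds.
- **Failures** are injected at the record level with probability
  `failure_rate`, default 0 (a randomly failed baseline would abort scaling
  calibration); tests exercise failures explicitly.
- An optional cosine **ripple** (amplitude default 0) adds local minima while
  keeping the global minimum at θ*, for exercising global search.

What passing tests on this truth do and do not show: they validate the
optimization loop, surrogate machinery, filtering, scaling, and statistics
end-to-end on a smooth, noisy, segmented landscape with a known answer; they
do not validate force-field transferability, real liquid-state physics, or
behaviour under the systematic (non-Gaussian, correlated) errors of real
property estimation.

### An intrinsic identifiability limit

Because the truth's residuals vanish at θ*, the residual Jacobian is zero
there and χ grows *quartically* in any single-coordinate displacement f:
Δχ ≈ (f/w)⁴ × (that key's variance share)², with w the key's fractional
sampling half-width. Detecting a 2% displacement of the hydrogen ε (w = 0.5)
therefore requires resolving χ to ~1e-6, while the default simulation noise
floor fluctuates near 1e-4 — and this ratio is invariant to the overall
curvature scale, since d_n rescales with it. Noise-free runs recover every
coordinate to well under 2% (validating the machinery); with default noise
the optimization reliably reaches χ ≈ 0.02–0.05 (a 20–50× improvement on the
baseline) but the weakly-identified coordinates plateau at roughly 3–10%
error. This is a property of the estimation problem, not of the optimizer.

## Analysis

Benchmarks report RMSE and MSD (mean signed deviation) overall, per property
type, and per functional group. Confidence intervals are 95% percentile
bootstrap, resampling molecules (mixture pairs for binary data) with
replacement, default 1000 resamples; percentile rather than BCa intervals
are used as the simplest stated choice. Surrogate robustness runs n_starts
(default 100) L-BFGS-B minimizations from uniform random starts inside the
bounds and reports SD_χ (standard deviation of the minima) and O_5% (the
percentage within 5% of the best). Cross-validation evaluates each ensemble
at independently found minima and reports the percent deviation from the
simulation χ; minima with zero simulation χ are reported as undefined (NaN).

## Numerical and reproducibility choices

- All randomness flows from one master seed through `derive_seed(master,
  *tags)` (CRC-32 of the tag tuple, reduced below 2³¹), so every component
  (LHS, GP restarts, DE, noise, bootstraps) has an independent, reproducible
  stream, and identical config + seed reproduce trajectory files byte for
  byte.
- Degenerate single-vector pools at η = 1 get an infinitesimally opened
  bounds box so downstream optimizers always receive a valid interval.
- GP fits reject pools with fewer than two distinct vectors; duplicated
  inputs with conflicting outputs surface as an ill-conditioning error after
  jitter escalation.
- Problem sizes used by the test suite and acceptance script (chosen as the
  package's own replicate scale): 28-compound pure sets, n_initial = 10,
  at most 15 iterations (25 simulations), 2 GP restarts, DE capped at 120
  generations; smaller 4-parameter spaces for fast unit tests.

## Known limitations

- The evaluator interface is synchronous and serial; no scheduling of
  concurrent simulations.
- No Bayesian-optimization acquisition (predictive variance is unused) and
  no gradient or reweighting information in the surrogates.
- Unit handling is by convention (g/mL, kJ/mol, kcal/mol, Å); inputs must
  already conform.
- The objective's absolute scale is anchored to χ(baseline) = 1; objective
  values from differently-scaled pipelines are not directly comparable.
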