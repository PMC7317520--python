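# Methods

## Model and assumptions

Medium concentrations in a stirred reactor evolve as
`dc/dt = P·ν(t)·X_v(t)` (batch), where `P` maps reaction fluxes to
external species, `ν` is the cell-specific flux vector and `X_v` the
viable-cell density.  Two assumptions make estimation tractable:

1. **Intracellular steady state.**  Internal metabolite pools are
   balanced, `N·V = 0`, so volumetric fluxes live in the null space of
   `N` (`V = K·U`) or, equivalently under irreversibility, in the cone
   spanned by the elementary modes (`V = E·R`, `R ≥ 0`).
2. **Piecewise-linear volumetric fluxes.**  `U(t)` (or `R(t)`) is linear
   between user-chosen inflection points.  Concentrations are then exact
   piecewise-quadratic integrals of hat functions, and the predicted
   value at any time is linear in the node values — no numerical
   differentiation of noisy data ever happens.

Residuals are standardized by per-point uncertainties `σ_ij`, giving the
weighted SSR that all solvers minimize.  Initial concentrations are
estimated jointly with the node values by default (`estimate_c0=True`);
pinning them to the first sample is available but biases the first
segment when that sample is noisy.

Irreversibility is imposed only at the nodes (`K_irr·U(T_j) ≥ 0`); since
`V` is piecewise linear, node feasibility implies feasibility for all
`t`.  The same argument covers `R_k(T_j) ≥ 0`.

## Solvers

All four problems are convex QPs solved deterministically without an
external QP library:

* unbounded — dense least squares (`numpy.linalg.lstsq`); rank
  deficiency raises unless the minimum-norm fallback is enabled.
* bounded — least squares with inequalities `G·x ≥ 0` via the
  Lawson–Hanson chain LSI → LDP → NNLS (`scipy.optimize.nnls`), an exact
  active-set method.  Requires a full-column-rank design.
* EM modes — the free initial-concentration block is projected out with
  a QR factorization, leaving a pure NNLS in the node rates; ridge rows
  `√α/X_v(T_j)` implement the regularization.  Rank-deficient EM sets
  (macro-reactions that are conic combinations of others — common, and
  the very motivation for regularizing) are handled by NNLS's vertex
  choice: the SSR is unique even when the rate split is not.

KKT residuals (stationarity, primal feasibility, complementary
slackness) are asserted in the tests at 1e-8/1e-9 scale.  The SSR
hierarchy `unbounded ≤ bounded = em(full, α=0) ≤ em(subset) ≤
em(subset, α>0)` is verified numerically; the bounded/full-EM equality
holds to ~1e-15 relative on the bundled fixtures.

`X_v(T_j)` in the penalty and in `r_k = R_k/X_v` uses linear
interpolation of the *measured* cell-density series, not the fitted
curve, keeping the problem quadratic.  Units: hours, mM, X_v in 10⁶
cells/ml; `specific_rates` takes a `volume_factor` (1e-3 converts the
plain ratio to mmol/10⁶ cells/h; default 1.0 reports the raw ratio).

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| inflection nodes `n_T` | 5, equally spaced | matches typical fed-batch practice; `n_T = 2` degenerates to one linear segment |
| α (regularization) | 0, or cross-validated | CV over time points, round-robin after seeded shuffle; ties break toward the larger α |
| CV folds | 3 | each fold must leave ≥ 2 points per species |
| bootstrap resamples | 500 | standard choice for stable 95% percentiles |
| bootstrap α | 0 | regularization would shrink the bands; an optional `conditioning_ridge` (~1e-10) only stabilizes degenerate EM sets |
| grid jitter | uniform, ±0.5 of the smaller adjacent spacing | removes the bias tied to one fixed grid; endpoints never move |
| noise model | σ = a + b·c, b = 0.05/1.96 | "95% CI = 5% of magnitude" convention; the 1.96 quantile is fixed |
| geometric reduction tolerance | 1% of the initial SSR | reduction stops before the re-solved SSR exceeds the budget |
| NSGA-II | pop 100, 200 generations, uniform crossover p=0.9, bit-flip p=1/n | standard settings for binary encodings; every SSR is cached by chromosome |
| rank tolerance | σ < 1e-10·σ_max treated as zero | standard numerical-rank practice |

Null-space basis convention: orthonormal from the SVD, each column's
sign fixed so its largest-magnitude entry is positive.  The basis is
not unique; fitted curves, SSR and `V = K·U` are basis-invariant
(tested), only the `U` coordinates depend on it.

## Elementary modes

Enumeration uses the double-description tableau on the pointed cone
after splitting reversible reactions, with combinatorial
support-minimality filtering; forward+backward two-cycle artifacts are
removed and split pairs recombined into signed patterns.  This is exact
and meant for small networks (≲ 30 columns after splitting; a
configurable mode cap advises external enumeration + `read_em_matrix`
beyond that).  Macro-reactions `P·v` are L2-normalized per column, the
convention under which a 1:1 conversion prints ±0.70711 and a 1:1:1
conversion ±0.57735.

Geometric reduction groups modes by connected components of the cosine-
similarity graph at a falling threshold schedule (1−1e-10, 0.9999, …,
0.7), keeps each group's medoid, and re-solves the EM problem after each
step, stopping before the SSR budget is exceeded.  The cluster-
representative rule and schedule are this package's own deterministic
choices; collinearity at cosine ≥ 1−1e-10 counts as an exact duplicate.

## Subset selection

NSGA-II with binary chromosomes (one bit per EM): fast non-dominated
sorting, crowding distance, binary tournament, uniform crossover,
per-bit mutation, and a repair step enforcing ≥ 1 active bit plus an
optional always-include mask (e.g. a biomass death-rate mode).  The
inner objective solves the EM problem at α = 0 per experiment and sums
SSRs unweighted across experiments.  A per-generation hypervolume trace
is recorded; an exhaustive enumerator (`pareto_front_exhaustive`)
provides the exact front for ≲ 12 modes and is the oracle in the tests.
The knee report flags the smallest subset within `(1+tol)` of the
bounded-DMFA lower bound.

## Bootstrap

Parametric residual-free resampling: every observed value is redrawn
from a Gaussian centred on it with σ from the noise model (negative
draws clipped at zero, count logged), the interior inflection points are
jittered, and the chosen solver re-run; failed solves are skipped (error
if > 20%).  Bands are empirical percentiles (median, 68%, 95%) per
quantity per evaluation time — percentile intervals, not BCa.  Each
sample uses an independent `SeedSequence` substream, so results are
reproducible for a seed regardless of execution order.  On the
linear-model fixture (truth inside the model class, full-rank EM set)
the measured 95%-band coverage of mid-process specific rates is ≈ 93–94%
over 200 replications of 50 resamples — slightly below nominal, as
expected for percentile intervals at this resample count.

## Synthetic data

The generator integrates `dc/dt = E·r(c)·X_v + (F/V)(c_feed − c) +
q_gas`, `dV/dt = F` (LSODA, rtol 1e-8; negative-concentration events
abort), with Monod-type kinetics optionally carrying non-competitive
inhibition.  Two bundled scenarios on a small CHO-like pyruvate-branch
network (glucose → pyruvate → lactate/biomass, glutaminolysis,
maintenance; 6 external species + X_v):

* `default_scenario` — fed-batch, exponential glucose/glutamine feed,
  reversible lactate exchange.  Its six EMs contain conic redundancies
  (overflow + reuse mimic direct growth), deliberately exhibiting the
  ill-conditioning that motivates regularization.
* `simple_scenario` — batch, irreversible lactate; its four EMs have
  mutually independent external signatures, so removing any active mode
  must strictly worsen the fit.

`piecewise_linear_fixture` generates data whose true volumetric rates
are piecewise linear on the fit grid with a full-column-rank EM matrix —
the controlled setting for recovery and bootstrap-calibration studies.

What the generator does *not* emulate: pH/temperature effects,
time-varying stoichiometry, sampling-volume removal, autocorrelated or
non-Gaussian assay errors, and a mechanistic gas-transfer model
(volumetric gas rates are user-supplied, mirroring how measured transfer
is compensated rather than modeled).  Passing tests therefore
demonstrate correctness of the estimators under the stated noise model,
not robustness to every artifact of real assays.

The pseudo-batch ("shifting") correction converts fed-batch data to
batch-equivalent per-reference-volume values,
`c_b(t) = [c·V − ∫F·c_feed − ∫q_gas·V]/V_ref`, with `V` reconstructed
from the feed rate (cumulative Simpson on a 2000-point grid) and sigmas
scaled by `V/V_ref`.  A quadrature round-trip against the simulator
closes to < 1e-6 relative when the trajectory itself is integrated
tightly (the default rtol 1e-8 dense output is the limiting factor
otherwise).

Rate-based baselines differentiate an interpolant of the data
(interpolating cubic spline, GCV smoothing spline, or a centered
moving-average filter whose half-width shrinks symmetrically at the
edges so linear trends stay unbiased), divide by `X_v`, and project onto
the EM cone by per-timepoint NNLS; a windowed (collocation-style)
variant stacks adjacent time points, approximating joint-fit methods
from the rate-based literature.

## Benchmark problem sizes

The shipped studies are sized for a single CPU: 13 sample times, 4–6
EMs, 4–5 inflection nodes, 20 benchmark replicates per noise level, 200
outer replications × 50 resamples for coverage, and exhaustive
enumeration of all 1023 subsets of the 10-mode selection instance.  All
are package defaults chosen to make the statistical comparisons stable
at interactive runtimes; each knob is a function argument.

## Known limitations

* EM enumeration is exact but exponential; production-scale sets
  (> ~10⁴ modes) must come from dedicated tools via `read_em_matrix`.
* Individual EM rates are not identifiable when macro-reactions are
  conically dependent; only the fitted concentrations and SSR are.
  Regularization selects the minimum-norm attribution, which is a
  modeling choice, not extra information.
* The bounded solver requires a full-column-rank design; heavily masked
  data with many nodes can violate this (the error message says so).
* Percentile bootstrap bands mildly undercover at small resample
  counts; 500 resamples is the recommended default.
* The geometric-reduction schedule and the windowed NNLS baseline are
  deterministic in-package interpretations of procedures that exist in
  several variants in the literature.
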