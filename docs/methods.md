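# Methods

This note documents the models, numerical procedures, simulation design and
known limitations of `lactofit`. It is written for a user who wants to know
exactly what the package computes and what the test suite does and does not
establish about real pastoral test-day data.

## 1. Data model

A *test-day record* is one once-daily milk measurement (g/day) for one goat
at an integer number of days in milk (DIM, 0-based on the kidding day).
A *lactation* is a DIM-sorted set of such records plus five categorical
covariates: herd (1–5), kidding year (1998–2000), kidding month (Jan, Feb,
Nov, Dec), litter size (single/twin) and dam age (1–8 years). These level
sets describe the pastoral population the package was built around and are
configurable for other populations. Readers never silently drop data:
malformed rows go to a rejection report with a reason code; duplicate
(lactation, DIM) pairs abort with the offenders listed.

## 2. Curve families

Nine families are registered. Time is continuous DIM in days; yields are
g/day; `0^0 = 1` so `B = 0` degenerates gracefully.

| name | form | params |
|---|---|---|
| wood | `A t^B e^{−Ct}` | 3 |
| yadav | `A + B/t + C t` | 3 |
| dhanoa | `A e^{−B(t−C)} e^{−2 e^{−D(t−C)}}` | 4 |
| wilmink | `A + B e^{−Dt} + C t` (decay `D` estimated) | 4 |
| cappio_borlino | `A t^{B e^{−Ct}}` | 3 |
| cobby_le_du | `A (1 − e^{−Bt}) e^{−Ct}` | 3 |
| morant | `A exp(Bτ + Cτ² + D/t)`, `τ = (t−150)/100` | 4 |
| goodall | `A t^B e^{−Ct} + D` | 4 |
| grossman | `A t^B e^{−Ct}(1 + D sin t + E cos t)` | 5 |

Notes on the less standard rows. Several published transcriptions of this
battery print multiplicative notation (`A × (days × B)`) where the curve is
only a lactation curve under the power reading; we implement the power
forms throughout, which for `cappio_borlino` gives the published
time-decaying-exponent model `A t^{B e^{−Ct}}`. `morant` is the
Morant–Gnanasakthy quadratic-exponential with the `((t−150)/100)²` term.
`goodall` takes its fourth parameter as an additive offset so that `D = 0`
collapses exactly to `wood` (asserted in tests; likewise `grossman` with
`D = E = 0`, and the linear collapses of `wilmink`/`yadav`).
`cobby_le_du` is implemented in its published form but excluded from the
default comparison battery: on sparse test-day data its `B` and `C` trade
off along a ridge and fits are not interpretable.

Parameter boxes (e.g. `A ∈ (0, 10⁵]` g/day, `B ∈ [0, 5]`, `C ∈ [0, 1]`
day⁻¹ for the gamma cores) serve two purposes: they keep every family
finite on `t ∈ [0, 400]` anywhere in the box, and they exclude sign-flip
degeneracies. All families carry analytic parameter Jacobians, verified
against central finite differences.

## 3. Fitting

Per-lactation estimation uses bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, TRF) with the analytic Jacobian.
Convergence: relative cost change < 1e−8 or step < 1e−10; cap 200
Jacobian evaluations per start; on failure, up to 3 seeded random restarts
perturb the start log-normally inside the box, and the best solution seen
is returned flagged `converged=False` if nothing terminated regularly. The
iteration count reported is the solver's Jacobian-evaluation count summed
over starts — the closest observable to a classical iteration counter.

Starting values: for the gamma-core families, ordinary least squares on
`ln y = ln A + B ln t − C t` over the strictly positive records (exact on
noiseless Wood data; zero yields are kept in the NLS objective but excluded
from the log start). `yadav` and (given a coarse grid on its decay rate)
`wilmink` start at their exact linear OLS solutions; `morant` log-linearises;
`dhanoa`/`cobby_le_du` use moment heuristics. Starts are projected into the
box.

A fit requires at least `n_params + 1` test days (one residual degree of
freedom); all-zero lactations are rejected as degenerate. `R²` is
`1 − RSS/Σ(y−ȳ)²`. Parameter covariance is the usual asymptotic
`(RSS/dof)·(JᵀJ)⁻¹` at the optimum (pseudo-inverse; near-aliased families
get honest, large standard errors).

Model comparison fits the battery to every lactation and reports, per
family: converged count, median iteration count, *pooled* `R²`
(`1 − ΣRSS / SST` over the concatenated records of converged fits — one
number per family, as model-battery tables conventionally print), mean
per-lactation `R²`, and total RSS. Ranking maximises pooled `R²` with RSS
as tie-breaker; families with no converged fit are excluded from the
ranking but still reported. Both pooled and mean `R²` are emitted because
the field's tables rarely say which they print.

## 4. Trait calculus

All traits are computed from the Wood fit and the recording calendar,
exactly as defined in §"The model" of the README. Numerical choices:

* `TP` uses the lower-incomplete-gamma closed form
  `A C^{−(B+1)} γ(B+1, C·t_end)` (g → kg at reporting); the adaptive
  quadrature route is kept as an independent cross-check and the two agree
  to 1e−6 relative over randomised parameter draws. The lower limit is
  kidding (t = 0); the integrand vanishes there for `B > 0` so the endpoint
  is benign, and `C = 0` falls back to the power-law primitive.
* `PD = B/C` requires `C > 0`; a non-declining curve raises `NoPeak`.
* `PC = 100 − (1−B) ln C` is implemented verbatim. It is scale-sensitive:
  with `C` in day⁻¹ (so `C < 1`, `ln C < 0`) it typically *exceeds* 100 %.
  A `c_scale` knob lets users evaluate it with `C` rescaled to other time
  units; it defaults to 1 (verbatim) and is never applied silently.
* Summaries use the n−1 SD and a Lilliefors-corrected KS normality verdict.
* Cohort summaries are means of per-lactation traits. Because
  `mean(B_i/C_i) ≠ mean(B)/mean(C)`, trait means cannot be reproduced by
  plugging parameter means into the trait formulas; the tests assert this
  inequality explicitly. This matters when comparing against published
  descriptive tables, which are not always internally consistent on this
  point (see §7).

## 5. Factor-effects screen

The five-factor additive fixed-effects model is fitted by OLS
(statsmodels). For the wildly unbalanced field design the default tests are
Type III sums of squares on sum-coded contrasts; Type I is available. The
significance encoding is `S` (p < 0.05), `HS` (p < 0.01), `NS`. Factors
whose contrasts are linearly dependent on earlier factors (confounding) are
reported as *inestimable* — never silently dropped; detection is by greedy
rank comparison in model order. Interactions are excluded by design (the
additive model is the screen, not a full factorial study).

Duncan's multiple range test uses protection levels
`α_p = 1 − (1−α)^{p−1}` with studentized-range quantiles
(`scipy.stats.studentized_range`); the least significant range for a span
of `p` ordered means is `q_{α_p,p,ν} · sqrt(MS_e/n_h)` with `n_h` the
harmonic mean of the two group sizes (Duncan–Kramer for unbalanced data).
The stepwise containment rule is enforced — a pair inside a wider span
already declared homogeneous is never declared separated — and letters are
assigned over means sorted descending ('a' = top group, as in livestock
tables). The grouping is validated against an exhaustive pairwise oracle
and the q-quantiles against classical Duncan significant-range tables.

Pearson correlations among traits carry two-sided p-value flags;
zero-variance traits yield missing entries, reported as such.

Normality screening uses the Kolmogorov–Smirnov statistic with the
Lilliefors correction (mean and SD estimated from the sample), accept at
p ≥ 0.05.

## 6. Synthetic data generator

The generator emulates fortnightly once-daily pastoral milk recording:

* per-goat `(A, C)` log-normal and `B` truncated-normal, parameterised by
  arithmetic mean and SD. Defaults: means (730 g/day, 0.26, 0.09 day⁻¹)
  and SDs (250, 0.04, 0.01) — the reported population-level values for this
  goat population;
* additive factor effects on `A` (and on `C` for kidding month), default
  magnitudes ordered like the field-level mean tables; effects are centred
  against the configured level frequencies, so switching effects on never
  shifts the population means;
* covariate frequencies mirroring the unbalanced field design (≈ 66/34
  single/twin; births concentrated in December; one herd dominant);
* lactation length truncated-normal, mean 146, SD 30.71, clipped to
  [62, 189] days, drawn independently of the curve parameters;
* records at DIM `first_test_day, +interval, … ≤ LL` (defaults 14, 14),
  with `yield = multiplier × (Wood(A,B,C;t) + N(0, noise_sd))` truncated at
  zero. `multiplier` (default 1) expresses the once-daily vs twice-daily
  recording convention (set 2 to double); `noise_sd` defaults to 50 g/day.

A fixed seed gives byte-identical output. What the generator does *not*
emulate: autocorrelated within-lactation residuals, seasonal pasture
trajectories within a lactation, dependence of lactation length on the
curve (a hook exists but defaults off), pregnancy effects, or pedigree
structure. Tests passing on this generator therefore certify the
*estimation and inference machinery*, not the adequacy of the Wood model
for any particular real herd.

## 7. Estimability of the reference recovery cohort

The reference cohort used by `scripts/acceptance.py` draws curves around
the reported population means (730, 0.26, 0.09 day⁻¹) with fortnightly
records from DIM 14. These reported values are mutually inconsistent with
the same source's curve characteristics: `B/C ≈ 2.9` days while the
reported mean peak date is 23.39 days, and the implied total production
(≈ 13.7 kg to DIM 146) is far below the reported ≈ 98 kg. Taken at face
value, a decline rate of 0.09 day⁻¹ puts the curve maximum *before the
first test day* and drives yields to ≈ 0 by DIM 60, so most records are
truncated measurement noise. Under these conditions the per-lactation
least-squares estimator is strongly mean-biased: `B` is essentially
unidentified from the sampled window (its estimates pile up on the bounds)
and `A` and `C` inherit heavy right tails. This was verified by simulation,
including fits started at the true parameters; it is a property of the
stated conditions, not of the optimizer. The acceptance script nevertheless
runs exactly these conditions and reports what it computes.

By contrast, with the decline rate that makes the same characteristics
self-consistent (≈ 0.011 day⁻¹, peak ≈ 24 DIM — the shape the population's
published curve figure shows), the identical pipeline recovers all three
parameter means within 3 Monte-Carlo SEM at 200–400 lactations; the test
suite's Monte-Carlo bias tests and the injected-effect recovery tests
therefore run in this identified regime. The persistency statistic's
scale-sensitivity (§4) is the same unit question seen from the trait side;
the package implements the printed formulas verbatim and exposes the
alternatives as explicit knobs rather than resolving the ambiguity
silently.

## 8. Problem sizes and other design choices

Simulation-based tests use 25–400 lactations per cohort, 100 replicates for
effect-recovery censuses and 500 for the ANOVA type-I calibration — sizes
chosen so each check has ample power while the whole suite stays quick on a
single CPU. Identifiers sort lexicographically (`L0001`, …); all pipeline
outputs are plain CSV plus a YAML provenance block embedding the full
generator config; the pipeline is a pure function of (inputs, config, seed)
apart from log timestamps.

Known limitations: no mixed/random-regression test-day models, no Bayesian
estimation, no genetic evaluation, no multiple-testing correction beyond
Duncan's protection levels, and no attempt to reconcile the unit
inconsistencies of §7 beyond documenting them.
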