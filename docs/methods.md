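# Methods

## Model

Time is grouped into intervals `[a_{t-1}, a_t)`, `t = 1..q_max`; choosing a
duration `q` means implementing the first `q` planned visits. Conditional on
being at risk at the start of interval `t`, a subject under covariates `x`
realizes one of `J+1` outcomes: event type `r` with cause-specific hazard
`λ_r(t|x)`, or survival of the interval with probability
`λ_{J+1} = 1 − Σ_r λ_r`. Survival and cumulative incidence follow by the
usual products and sums: `S(t|x) = Π_{s≤t} λ_{J+1}(s|x)`,
`F_r(t|x) = Σ_{s≤t} λ_r(s|x) S(s−1|x)`, with `S(0|x) = 1`.

Two links are implemented. The **multinomial logit** gives each cause its
own predictor `η_r = γ_{0tr} + f_r(x)'γ_r` relative to conditional survival;
the **cumulative logit** (for ordered causes) puts shared-effect logits on
the cumulative cause probabilities, with intercepts required to be
non-decreasing in `r` — violations are rejected at construction, never
silently repaired, because a silent reorder would corrupt calibrated
baselines. Covariate maps receive `(x, t)`, so linearly time-varying
treatment effects (`f_r(x, t) = (x, x(t−1))`) are ordinary configurations.
Baselines are either saturated (one coefficient per period and risk) or a
per-risk basis expansion (polynomials in a rescaled time are provided).

The parameter vector stacks the baseline block (time-major), the effects,
and a fixed **structural zero**: the predictor of the reference (survival)
category. It is retained as a genuine coordinate. The unified link
`C' log(L λ) = X_t θ` is differentiated as
`∂λ/∂θ' = (C' D⁻¹ L)⁻¹ X_t`, `D = diag(L λ)`, which extends the hazard map
*off* the probability simplex through that coordinate: the extension is what
makes the per-period information matrix nonsingular in all `qJ + p + 1`
coordinates. One consequence worth knowing: the Jacobian's structural-zero
column does not equal a finite-difference derivative of the simplex-bound
hazard function (softmax is shift-invariant in that direction), and its
column sum is 1, not 0. All other columns agree with central finite
differences to the expected order, and the free block of the information
equals the negative expected Hessian of the person-period log-likelihood;
both facts are tested.

## Information, costs, criteria

Per-subject group information over `q` periods weights each period's
information by the expected at-risk fraction `S(t−1|x)(1−ρ)^{t−1}`, with a
constant per-interval attrition probability `ρ` (the per-period general form
exists internally). The cost-standardized information is
`M^c = Σ_i π_i M(x_i) / Σ_i π_i c(x_i)` — information per unit of
(net-of-setup) expenditure; it is independent of the total budget and sample
size, which re-enter only through `N = (C − c0) / Σ_i π_i c(x_i)`.

Two per-subject cost functions are available with recruitment cost `c1` and
measurement cost `c2` (configured via the ratio `f = c1/c2`, `c2 = 1`):

* `all_visits`: `c1 + c2 (q + 1)` — every scheduled visit is charged;
* `until_event`: `c1 + c2 Σ_{s=1}^{q} S(s−1|x)(1−ρ)^{s−1}` — only visits a
  subject actually attends. The intake measurement at `a_0` is **not**
  charged by default; `CostSpec(baseline_measurement=True)` adds it. The
  no-intake-charge convention is the one under which the package's duration
  panels agree with the published ones cell for cell, and it only shifts all
  per-subject costs by `c2`, so it matters mostly at small `f` and small `q`.

Designs are ranked by `Φ_A = log |A' (M^c)⁻¹ A|`, with `A = I` (D), the
effect block (Ds), or a per-risk effect subset. Ranking and relative
efficiency use the per-parameter scale `Φ_A / v` (`v = rank A`): for a fixed
selection matrix this is a monotone relabelling, but for D-optimality with a
saturated baseline the dimension of `θ` grows with `q`, and only the
`v`-th-root (geometric-mean variance) scale makes durations comparable.
Relative efficiency of `ζ` against the optimum `ζ*` is
`exp(Φ(ζ*)/v* − Φ(ζ)/v)`; 0.5 means `ζ` needs twice the budget. A singular
`M^c` yields `+∞` (the cell is infeasible) rather than an exception, so
searches never abort on individual cells; a search aborts only when *every*
candidate is infeasible. The delta-method variance of a plug-in cumulative
incidence estimate (the c-criterion objective) uses a central-difference
gradient in `θ` with step `1e−6·max(1, |θ_j|)`; the structural zero is never
perturbed.

## Search

The candidate grid is exhaustive: durations `q ∈ {1..q_max}` crossed with
allocation weights on the simplex in steps of 0.01, excluding zero-weight
arms (a single-arm design cannot estimate treatment contrasts); for two arms
and `q_max = 12` this is the 1188-design grid. Per-period weighted
information matrices are precomputed once per scenario in the full-duration
layout and truncated per candidate `q` by index selection, so each grid cell
costs one small determinant. Ties within `1e−10` are broken by smaller `q`,
then by allocation closest to equal — the published tables do not state a
tie rule, and this prefers cheaper, balanced designs. Identical inputs give
bit-identical grid tables.

## Weibull calibration of nominal baselines

Locally optimal designs need nominal parameter values. Baseline coefficients
are calibrated from a two-risk Weibull mixture for the control-arm CIFs,

    F_1(t|0) = κ (1 − exp(−λ₁ t^τ₁)),   F_2(t|0) = (1−κ)(1 − exp(−λ₂ t^τ₂)),

with scales set via event fractions, `λ_r = −log(1 − w_r)`. Discrete
hazards come from CIF increments over the inspection grid divided by the
**cause-specific** survivor `1 − F_r(a_{t−1})` (the package default); an
`overall`-survivor variant (`1 − F_1 − F_2`), which makes the discrete model
reproduce the parametric CIFs exactly, is a documented switch. Inverting the
link then gives `γ_{0tr}`. The calibration is computed entirely in log
space: with increasing-hazard shapes (`τ > 1`) the Weibull tail probabilities
underflow double precision well inside a 12-period grid while the log
hazards stay representable (baseline coefficients of −500 and below are
legitimate values, not errors). If a period's hazards ever sum to ≥ 1 the
calibration is rejected with the offending period named. When a hazard
underflows to exactly zero, a saturated model is exactly singular from that
period on; the search marks those durations infeasible.

**Time scale.** The sensitivity-study scenarios place the inspection grid at
`a_t = t/q_max`, i.e. the Weibull mixture runs on the study-duration scale
and `w_r` is the fraction of control subjects with a risk-`r` event by the
*end* of the horizon. On a raw per-month scale, shapes `τ = 3` exhaust the
entire cumulative incidence within three months and long durations could
never be optimal, contradicting the published duration panels; the
study-duration scale reproduces all 48 of them. The grid spacing is
configurable (`weibull.time_scale: months` in a scenario file restores unit
spacing).

## Trial-redesign scenario (80-month horizon)

The antiepileptic-drug trial redesign uses quadratic polynomial baselines
`γ_{0tr} = γ_{00r} + γ_{01r}u + γ_{02r}u²` with `u = t/80` and the published
point estimates as nominal values. The raw-month polynomial is numerically
degenerate with those coefficients (predictors of order −20000 at the
horizon); the `t/80` rescale yields the published rise-then-fall logit
hazards and reproduces the published optima. The rescale factor is
configurable. The published criterion-value column equals our `Φ/v + log 2`
— a per-subject cost unit twice ours, which rescales the criterion by a
constant and cannot change any optimum; the package reports raw `Φ` and
`Φ/v`.

## Simulator and estimation

The simulator draws each at-risk subject's period outcome from the
multinomial hazard vector; attrition acts *after* the outcome assessment
(a subject can fail in the period they would have dropped), matching the
risk-set weights `S(t−1)(1−ρ)^{t−1}` used by the information machinery.
Group sizes are `Nπ_i` rounded by largest remainder. Records are aggregated
to `(group, period, outcome)` counts, so likelihood, analytic score and
fitting cost do not grow with `N`. The fitter is BFGS on the free
coordinates with analytic score (gradient tolerance `1e−8`, Nelder–Mead
fallback), the structural zero held fixed; observed information is the
central-difference derivative of the analytic score at the optimum;
coordinates beyond |30| are flagged as separation. The recovery study
reports per-coordinate bias, the ratio of empirical to information-predicted
variance, and 95% Wald coverage, and aborts if more than 5% of replicates
fail to converge. Its default validation scenario (unit Weibull shapes, 6
periods, equal split, `N = 2000`, 300 replicates) runs in about 1.5 minutes
on one CPU; with 300 replicates the Monte-Carlo standard error of a variance
ratio is ≈ 0.08 and of a coverage proportion ≈ 0.013, which is what the
test tolerances reflect.

## What the synthetic data do and do not show

The generator emulates exactly the process the design theory assumes:
multinomial interval outcomes, independent subjects, geometric
non-informative attrition, time-constant covariates (or deterministic
time-varying effect structures). Passing recovery and coverage checks shows
the information matrix and criterion are correct *for this model*; they say
nothing about misspecified baselines, informative dropout, interval-censored
continuous processes, or frailty — all outside scope.

## Known limitations

* Free-allocation reproduction of the published two-arm tables is partial:
  all optimal durations and the decreasing-hazards panel's `(π*, q*, RE)`
  triples reproduce at printed precision, but in scenarios with an
  increasing-hazard risk (and in the "both effects +2.5" cells) the
  criterion surface is flat to under ~1% near the optimum and our argmin can
  sit 0.01–0.13 away in `π` from the printed one, with relative efficiencies
  differing by ≤ 0.03. The package's formulas follow the printed definitions
  exactly (per-group survival in the event-truncated cost, cost-weighted
  standardization, link-based treated-arm hazards); the residual difference
  is confined to those flat regions and the source convention could not be
  identified from the published material alone.
* Design optimization is over the finite grid only — no continuous-design
  algorithms or equivalence-theorem certificates; the inspection instants
  themselves are fixed, only their count is chosen.
* Locally optimal designs only: no Bayesian or minimax robustification over
  the nominal parameters.
* The cumulative-logit inversion cannot resolve hazards below about `1e−12`
  (differences of inverse logits hit double precision).
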