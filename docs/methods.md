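# Methods

`lifetab` estimates period life expectancy (LE) and Sullivan healthy life
expectancy (HALE) for subpopulations — here, registered disability groups
compared against a non-disabled reference — from age-specific exposure/death
schedules and unhealthy-prevalence schedules. This note records the model, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic ground truth does and does not establish.

## Life-table construction

For each sex × group block the chain is:

1. **Central death rates.** `mx = Dx / person-years`. Ages with zero exposure
   are *missing*, never zero; negative counts are rejected outright.
2. **Death probabilities.** `qx = mx / (1 + (1 − ax) mx)`, capped at 1. The
   separation factor `ax` (mean fraction of the year lived by those dying in
   it) is the Coale–Demeny infant value at age 0 — 0.05 for males, 0.13 for
   females, reflecting the early clustering of infant deaths — and 0.5 at all
   later ages, consistent with the midpoint person-years formula
   `Lx = (lx + lx+1)/2` used downstream.
3. **Graduation.** `qx` is smoothed by a symmetric local least-squares cubic
   over a 9-point window (`scipy.signal.savgol_filter`, `polyorder=3`,
   `mode="interp"`). This is the defining property of Greville-type
   graduation formulas: polynomials up to degree 3 — constants included — pass
   through unchanged, while isolated noise is attenuated. Endpoint ages are
   handled by evaluating the boundary-window polynomial, i.e. a one-sided fit.
   Published graduation coefficients can be dropped in via the `weights`
   argument; window widths 7 and 9 give near-identical tables on smooth
   schedules (the `smoothing neutrality` test bounds the LE effect at 0.5 y).
   Series shorter than the window pass through unchanged with a warning.
4. **Recursion.** `dx = lx qx`, `lx+1 = lx − dx`, `Lx = lx+1 + ax dx`,
   `Tx = Σ_{y≥x} Ly`, `ex = Tx / lx`, radix 100 000 by convention. The last
   supplied age opens the terminal interval: `q = 1` there and its
   person-years use the exponential closure `L_ω = l_ω / m_ω` with `m_ω` the
   (possibly model-extended) rate at that age; when no closure rate exists the
   triangular fallback `L = ax·l` is used and logged.
5. **Uncertainty.** Chiang's estimator:
   `S²_pj = q²_j (1 − q_j) / D_j` and
   `S²_ex = l_x⁻² Σ_j l²_j [(1 − a_j) + e_{j+1}]² S²_pj`,
   with 95% intervals `ex ± 1.96 se`. The bracket is squared, as in Chiang's
   published form; an `square_bracket=False` flag reproduces the unsquared
   literal variant for sensitivity analysis only. Ages with `q ∈ (0,1)` but no
   death count (e.g. model-extrapolated ages) contribute zero variance, with a
   warning. Intervals are computed at every age; reporting layers may subset.

Invariants enforced by tests: survivorship is monotone, all radix deaths are
conserved, rebuilding `Tx`/`ex` from `Lx` reproduces the stored columns bit for
bit, and one year of age never costs more than one year of remaining
expectation. Against a brute-force geometric-summation oracle, constant-hazard
tables agree to 1e−9 relative; over 500 Monte-Carlo replicates of a binomial
death process the 95% interval for e0 covers the large-sample truth ~95% of
the time (the acceptance band is 93–97%).

## Old-age extension

Observed rates at the oldest ages are noisy (small exposures), so rates from a
configurable `splice_age` (default: fit-window end + 1) upward are replaced by
a parametric hazard fitted on a window of reliable ages — default 65–84 for
subgroup tables, 75–94 appropriate for very large populations, both
configurable. Nine candidate families are registered (Gompertz, Makeham,
Kannisto, the Heligman–Pollard old-age term, Perks, Weibull, Coale–Kisker,
Denuit–Goderniaux, unconstrained log-quadratic); the registry is open, so a
different published set can replace any entry. Every family is fitted by least
squares on log mx over the same window — scale-appropriate for rates and
comparable across families — and the minimal criterion wins. Ties within
1e−12 go to a fixed priority order that places each constrained family ahead
of families nesting it (e.g. Gompertz before log-quadratic, Kannisto before
Perks), so exact-recovery is well defined. Families that fail to converge are
excluded with a warning; a per-group family override (e.g. forcing
Coale–Kisker for a general population) is a config key.

Fitting notes: Gompertz, Kannisto, Heligman–Pollard, Weibull, log-quadratic
and Denuit–Goderniaux linearise exactly (log, logit or constrained-basis least
squares); Makeham and Perks use a deterministic profile over the growth rate
with a non-negative linear inner solve, then a bounded refinement kept only if
it improves the criterion — fixed starting points make the whole stage
deterministic. Coale–Kisker is implemented as a log-quadratic with the rate
pinned to 1.0 at age 110 (the classical male closure value; configurable),
which encodes its constant-deceleration-of-mortality-increase idea with two
free parameters. Denuit–Goderniaux closes at age 130 with one free parameter.

Splicing keeps observed rates below `splice_age` untouched. To avoid a jump,
the log-rate offset between the last observed rate and the model at that age
is tapered linearly to zero over `blend_width` years (default 5; 0 = hard
splice). Observed death counts at replaced ages still feed the Chiang
variance; extrapolated ages contribute none. With data generated from a
family and extended by it, e65 agrees with the piecewise-constant-hazard truth
integrated to age 110 within 0.005 y (acceptance bound 0.2 y), and LE at
birth moves by < 0.05 y relative to using the true rates.

## Sparse-type imputation

Small disability types lack deaths at many ages. Missing age-specific rates
are borrowed from the pooled (standard) table through a logit-scale linear
link, `logit(mx_type) = a + b·logit(mx_standard)`, fitted by ordinary least
squares (statsmodels OLS; exposure-weighted WLS available) on the ages both
series observe with rates strictly inside (0, 1). "Logistic regression"
between two rate series is read this way because rates are proportions and no
death counts exist at the missing ages to weight a GLM; the logit link keeps
predictions in (0, 1) and is monotone for `b > 0`. With fewer than 3 usable
ages the link degenerates to a constant logit offset (slope 1, a pooled ratio
in the small-rate regime), logged. Observed cells are never altered.
Imputation is always per sex — the standard tables are sex-specific
throughout. Standard-table rates outside (0, 1) (the closure age) are clamped
into the link's domain before transforming.

Across nine synthetic types with hazard ratios 0.8–4.0 and 20–50% of ages
masked, the median absolute LE error at the first age is ~0.2–0.3 y
(acceptance bound 0.6 y).

## Abridged tables

Reporting collapses complete tables to 5-year groups (0, 5, …, 85+). `ex` and
its standard error at a group start are the complete-table values at that
exact age — abridging is a pure reporting view, never a re-derivation from
grouped rates — so abridged e0 equals complete e0 exactly. Group starts below
a type's first registrable age are clamped to it (e.g. a type registrable from
age 12 starts its first group there). Full double precision is kept
internally; 2-decimal rounding happens only at display, and the difference
report carries both a full-precision and a "printed-precision" column (the
latter differences 2-decimal-rounded inputs, matching how published tables are
subtracted).

## Sullivan HALE

`HALE_x = Σ_{i≥x} L_i (1 − π_i) / l_x`, the open interval included with its
own π. Three prevalence definitions are supported: DF (≥ 2 weeks of illness,
survey), PH (poor/very poor self-rated health, survey), NHIS (≥ 7 hospital
days, claims). The DF wording can denote a mean day-fraction rather than a
proportion of persons; the schedule abstraction accepts either, since both are
a per-age value in [0, 1]. Grouped survey prevalence is expanded to single
ages as a step function (assumption-light and reproducible); a monotone PCHIP
spline through group midpoints is available behind a flag. Ages below the
youngest survey group inherit its value (logged) because registration ages can
precede survey age bins; uncovered older ages are an error.

The default 95% interval treats prevalence as fixed and propagates mortality
sampling variation only: Chiang's recursion with `e_{j+1}` replaced by
`HALE_{j+1}` and the within-interval term scaled by the healthy fraction,
`[(1 − a_j)(1 − π_j) + HALE_{j+1}]²`. With π ≡ 0 this reduces exactly to the
LE interval. A binomial prevalence-variance term
`Σ (L_j/l_x)² π_j(1 − π_j)/denom_j` can be switched on when survey
denominators are available; it is off by default, matching the near-zero HALE
interval widths that fixed-prevalence reporting produces. Identities enforced
by tests: π ≡ 0 ⇒ HALE = LE and π ≡ c ⇒ HALE = (1 − c)·LE, both to 1e−12;
HALE is pointwise antitone in π; unhealthy LE = LE − HALE = Σ L_i π_i / l_x.

## Synthetic ground truth

The real registry/claims/survey inputs are restricted, so the generator
supplies fully specified study conditions: Gompertz–Makeham adult mortality
`μ(x) = A + B cˣ` with proportional subgroup hazard ratios; person-years from
a stationary-population shape (proportional to survival) scaled to a target
total; Poisson deaths given person-years (inputs are exposure-based);
group-specific first (registration) ages; seeded random blanking of age cells
for sparse types; and logistic age-increasing prevalence curves per HALE
definition. `analytic_le` integrates `exp(−∫μ)` on a 0.01-y grid to
`max_age + 10` and is the oracle for recovery tests; everything is
deterministic under the scenario seed and scenarios round-trip through YAML.

The default scenario's hazard was calibrated once so the male reference e0 is
81.3 y, with the pooled disabled group at hazard ratio 3.2 (e0 ≈ 68.5 y) and
exposure totals of registry magnitude (1.2e8 reference, 7.3e6 pooled,
4.5e4–7.5e5 for types). The crossover scenario gives the reference group a
steeply rising unhealthy share after age 70 (ceiling 0.97) while the disabled
group's plateaus (ceiling 0.34), reproducing the qualitative old-age reversal
of the HALE gap; the simulated crossover lands at age ~78.

What the generator does **not** emulate: the real age pyramid (stationary
shape instead), cohort effects and registration-year heterogeneity, survey
nonresponse, delayed death reporting, and within-group heterogeneity beyond a
single hazard ratio. Passing recovery tests therefore demonstrates that the
estimation chain is self-consistent and unbiased under proportional-hazards
conditions at realistic sample sizes — not that any particular published
estimate is correct.

## Problem sizes and determinism

Tests and the acceptance script run the chain at the scenario's default
exposure scales, nine-family recovery on 55-age noiseless schedules, the
imputation study at 3e5 person-years per type, and interval coverage with 500
binomial replicates of a ~4 000-person stationary cohort; the whole suite
completes in seconds. All randomness flows from explicit seeds; re-running a
study with the same config and inputs is byte-identical.

## Known limitations

- Period LE only: no cohort tables, no projection, no delayed-report
  estimation.
- The exact published set of nine extension families and the office's exact
  Greville coefficients and selection criterion are not public; the registry,
  the local-cubic graduation and the log-rate SSE criterion are documented
  stand-ins chosen to reproduce their defining properties.
- The Sullivan estimator inherits its usual caveat: it mixes current mortality
  with current prevalence and is not an incidence-based (multistate) health
  expectancy.
- The constant-offset link fallback for types with < 3 observed ages is crude;
  such groups should be interpreted with care.
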