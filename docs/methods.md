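# Methods

## The measurement problem

In a regulated health-insurance market the regulator organizes
cross-subsidies from low-risk to high-risk insured through risk-adjusted
equalization payments plus premium-rate restrictions.  When the
equalization formula is imperfect, groups of insured are predictably
under- or overcompensated, which gives consumers and insurers incentives
for risk selection: actions with the goal or the effect that the
intended cross-subsidies are not achieved.  The regulator's measurement
problem is that the obvious statistic — each insurer's mean residual
expenses — confounds selection with the insurer's *efficiency*: an
insurer can show negative mean residuals because it selected
overcompensated members, or because it buys care cheaply, and the two
are observationally equivalent at the portfolio level.

This package implements the estimators that address the problem (group
compensation statistics, overrepresentation indices, the naive insurer
mean, and the efficiency-unconfounded switcher estimator) together with
a market simulator whose ground truth makes their properties testable.

## Simulator

One simulated market is a two-year panel (years *t*−1, *t*) of
`n_persons` individuals across `n_insurers` insurers.

**Population.**  Each person draws independent categorical risk
adjusters.  The defaults emulate the demographic and morbidity blocks of
a Dutch-style equalization model: six age bands, sex, four regions, and
a chronic-condition flag with prevalence 31.5%.  Effects are log-linear
multiplicative on the positive expense mean (chronic ≈ ×3, 75+ ≈ ×2.1,
…), with the intercept solved in closed form so that mean annual
expenses equal `mean_expenses` (default 1570 currency units, an abstract
"euro").

**Unpriced health component.**  The quantity the equalization formula
cannot see, and the source of all selection incentives, is a per-person
euro-scale shift *u* with population mean zero:

* a fraction `prob_affected` (default 0.8) of the chronic subpopulation
  draws *u* = `scale` · (Gamma(`k`) − `k`) with `k` = 2, `scale` = 500
  (sd ≈ 707 €, right-skewed, bounded below at −1000 €); everyone else
  has *u* = 0.

This mirrors how real formulas fail: the morbidity flag prices the
*average* chronically ill person, but severity *within* the flagged
group is unpriced, so a minority of carriers is strongly
undercompensated (the default yields a "u > 0" group of ≈10% of the
population with mean overcompensation ≈ −650 € and predictive ratio
≈ 0.84) while the complement is mildly overcompensated.  Because *u* is
centered within the carrier cell it is orthogonal to every adjuster
dummy, which has two consequences: the OLS fit is asymptotically
unaffected by it, and the ground-truth overcompensation of any group is
exactly −(group mean *u* − population mean *u*).  The bounded left tail
also makes "the configuration implies a negative expense mean" a
deterministic configuration error rather than a random runtime failure.

**Expenses.**  A two-part model, standard for healthcare costs.  A
person-year is zero with probability p₀ (default marginal 19.5%; 2% for
the chronically ill, with the non-chronic probability solved to keep the
marginal); otherwise expenses are Gamma with mean
exp(η(x)) + u/(1 − p₀) — so the *unconditional* mean shifts by exactly
*u* euro — and shape 0.5 (coefficient of variation √2, in the range
reported for covariate-adjusted cost regressions; the implied marginal
residual sd is ≈ 3300 €).  The enrolled insurer's efficiency multiplier
scales the positive part only, keeping the zero mass interpretable as
utilization.

**Switching and selection.**  Year-(t−1) membership follows configured
market shares (default equal).  Each person switches with probability
`switch_rate` (default 0.031 ≈ a few-percent annual switching market);
optionally the decision to leave insurer *j* is tilted on *u* through a
logistic weight (`exit_strength`).  A switcher's destination among the
other insurers has weight share<sub>j</sub> ·
exp(s<sub>j</sub>·u + a<sub>j</sub>·|u|).  The linear tilt
s<sub>j</sub> < 0 courts the overcompensated (healthy); the |u| tilt
a<sub>j</sub> > 0 attracts *both* tails at once.  A single
enrollment-propensity mechanism of this form reproduces, at the level of
observable outcomes, all four action types (insurer- vs consumer-driven,
goal vs effect) — these are not separable observationally, which is
precisely why the scenario presets label mechanisms for documentation
only.  `calibrate_inflow_selection` inverts the tilt numerically
(quadrature over the *u* mixture + Brent root-finding) so a scenario can
target an exact expected ground-truth inflow overcompensation.

**Random-number discipline.**  Population, switching, and expense draws
use three independent child streams of the config seed.  Efficiency is
applied as a deterministic multiplier *after* the gamma draw.  Hence
changing one configuration block (say, one insurer's multiplier) leaves
all other draws bit-identical — counterfactual comparisons use common
random numbers exactly, which is what makes the efficiency-invariance
property testable bit-for-bit rather than statistically.

## Equalization fit

Unweighted individual-level OLS of expenses on intercept + dummy-encoded
adjusters, fit per year (numpy normal equations; the dummy Gram matrix
is tiny and well conditioned; an independent statsmodels cross-check is
kept in the test suite).  Declared levels with zero observations are
dropped with a warning; rank deficiency raises an error naming the
collinear columns; levels unseen at prediction time map to the reference
level and are counted, so prediction is total.  `overall_mean` *m* is
the fit-year mean of actual expenses (equal to mean predicted in-sample).
Predicted values and payments may be negative (a payment *to* the fund).
A model can also be supplied as fixed JSON coefficients and applied
without refitting — required for exact efficiency-invariance
comparisons, and the natural mode for a regulator applying an
externally estimated formula.  Cost scope (e.g. excluding mental-care
costs) is a property of the input panel, not of the model object.

## Estimators and tests

All estimators report overcompensation (= −residual); residuals appear
only in debug output, keeping one sign convention throughout.

* **Group compensation**: mean overcompensation, predictive ratio,
  and the reduction versus no equalization,
  1 − |O<sub>model</sub>| / |O<sub>none</sub>| with O<sub>none</sub> =
  *m* − mean actual (rendered as a negative percentage, the convention
  of published tables).  Groups are caller-supplied boolean predicates;
  the built-ins define membership on year-(t−1) information and evaluate
  year-t residuals.
* **Overrepresentation**: (group share within insurer) / (population
  share), exact binomial test.
* **Naive insurer estimate**: portfolio mean overcompensation with SE
  and t-test; kept deliberately, documented as efficiency-confounded.
* **Switcher estimates**: inflow = mean year-(t−1) overcompensation of
  an insurer's joiners; outflow = mean year-t overcompensation of its
  leavers; inflow uses the year-(t−1) model, outflow the year-t model
  (or one supplied model for both).  Cells with fewer than two switchers
  are marked unavailable.  Default ordering follows the published
  convention (decreasing non-switcher mean residual in year *t*); the
  mirror-image overcompensation ordering is available by flag since the
  published sign direction is ambiguous.
* **Significance**: two-sided one-sample t-tests against zero (normal
  approximation above n = 10⁴); zero-variance samples return p = 1 with
  a degenerate flag.  Observations are treated as independent — no
  adjustment for within-person correlation across years — and no
  multiple-testing correction is applied across insurers (stars are
  per-insurer, as in published tables); a Bonferroni toggle exists for
  the group table.

Persons present in only one panel year (entrants, leavers, deaths) are
excluded from switcher analysis and tallied in the run manifest.

## Scenario presets and their sizing

Five presets, each 200,000 persons so that a full scenario runs in
seconds and 100-replicate studies in minutes: `null-market` (25
insurers, everything off), `efficiency-bias` (5 insurers, multipliers
0.9–1.1, no selection), `recovery` (selection calibrated so insurer 1's
expected inflow overcompensation is +100 €), `cancel-out` (insurer 1
attracts both *u* tails, a₁ = 0.002), and `unsuccessful-selection`
(identical tilt for every insurer — the weights cancel in the
destination choice, so compositions stay equal although every insurer
"acts").  The recovery preset uses equal efficiency multipliers: its
purpose is validating the estimator against ground truth, and with few
insurers unequal efficiency shifts switcher residuals through the
*other* insurers' mean efficiency (see limitations), which would
contaminate the recovery target with a bias that is not the estimator's.

## What passing tests do and do not show

The simulator reproduces the statistical *structure* the estimators
assume — zero-inflated heavy-tailed costs, unpriced within-group
heterogeneity, efficiency as a multiplicative portfolio effect,
health-tilted switching — but not several features of real claims data:
cost persistence within person across years (expense draws are
independent given the profile), entry/exit and death, insurer-level
premium responses, plan-level (sub-insurer) segmentation, and group
contracts.  Parameter recovery here therefore validates the estimators'
logic and calibration, not their robustness to those real-world
complications; in particular, plan-level selection that cancels at the
insurer level is invisible by construction, exactly as it is in real
insurer-level data.

## Numerical choices and limitations

* Tolerances: in-sample residual-sum and budget identities are asserted
  to 10⁻⁸ relative; overcompensation = −residual and the predictive-
  ratio identity are exact float identities.
* Destination sampling uses cumulative-weight inversion with exponent
  clipping at ±30 to avoid overflow under extreme tilts.
* With k insurers, an insurer's switcher residuals are generated at the
  *other* k−1 insurers, whose mean efficiency is (kμ − eff<sub>j</sub>)/(k−1),
  not exactly the national mean.  The switcher estimator is therefore
  exactly invariant to the insurer's *own* efficiency but only
  approximately centered when efficiency dispersion is large and k is
  small: with k = 5 and multipliers 0.9–1.1 the null means shift by
  roughly ∓(1 − eff<sub>j</sub>)/4 · 1570 ≈ ±20–40 €, inflating the
  extreme insurers' test size to ≈ 0.06–0.09.  At a realistic k = 25 the
  shift is five times smaller and test size is nominal (the null-market
  calibration study).  Regulators applying the method to concentrated
  markets should interpret small switcher stars accordingly.
* The per-replicate sampling error of a switcher estimate at the preset
  scale is ≈ residual sd / √(inflow count) ≈ 3300/√1300 ≈ 90 €; studies
  that need ±10 € precision on a mean therefore require on the order of
  300+ replicates or proportionally larger panels.
* The expense distribution, switching process and market shares are
  simulator choices — real systems publish none of them — and are
  deliberately configurable; the defaults above are one internally
  consistent calibration, not an estimate of any particular market.
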