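# Methods

## Prediction model

All four dose models are ordinary least squares with an intercept, solved
via statsmodels on an SVD-checked design (rank deficiency is declared below
a relative singular-value tolerance of 1e-10 and reported with the first
redundant column). The residual standard error is s = √(RSS/df) with
df = n − p − 1 coefficients counted including the intercept. No
through-origin, robust or weighted variants are offered: the relation
between early- and late-cycle kidney doses is adequately linear over the
clinical dose range, and plain fits keep the prediction law exact.

Predictions are for a *single new patient*, so the prediction standard
error is s·√(1 + x₀ᵀ(XᵀX)⁻¹x₀) — strictly larger than s — not the
mean-response error s·√(x₀ᵀ(XᵀX)⁻¹x₀). The exceedance probability of a
threshold T given known cumulative dose K is P(T_df > (T − K − ŷ)/SE), an
upper-tail Student-t probability; it is one-sided because the clinical
question ("will the cumulative dose exceed T?") is directional. When
s = 0 (noiseless fixtures) the law degenerates to a step function with
probability ½ exactly at the margin, so deterministic test cohorts flow
through the planner unchanged.

Residual diagnostics are the Lilliefors normality test (statsmodels, table
p-values) and a Wald–Wolfowitz runs test about the median (statsmodels,
with continuity correction — without it the null rejection rate at n = 100
is ≈ 0.07 rather than ≈ 0.05).

## Risk policy

Two asymmetric risk levels drive every decision: cycles are *cleared* when
the exceedance probability is below 10%, and *precluded* when it is above
95% (a 5% error rate for denying a cycle). Denying an effective treatment
is graded more strictly than allowing one because the toxicity threshold
itself is uncertain while treatment efficacy is established. Both levels
and the 25 Gy threshold are configurable (`RiskPolicy`); a 29 Gy threshold
reproduces the sensitivity analysis.

Zone boundaries (exactly 10% or 95%) are assigned to the intermediate
zones B/E — continued monitoring is the conservative failure mode. After
cycle 2 the zone pair resolves with stopping conditions checked before
clearances: F → stop, C∩D → give exactly three cycles, A → clear four,
E → individual review, otherwise (B with D) → continue scanning. The
branch order is chosen so that stopping conditions are always evaluated
before clearances. Individual-review outcomes are emitted as labels and
never auto-resolved. Under the caution ordering
clear-four < continue-scanning < cap-at-three < review < stop
the recommendation is monotone in every observed dose (property-tested):
each action responds to a strictly higher dose-risk situation than the one
before it. After cycle 3 the fourth cycle is decided from the D4 model
with the same asymmetric levels.

T₁, the largest D1 below which four cycles are cleared, is found by
bisection to 0.001 Gy on the exceedance probability (monotone in D1 for
positive-slope fits); in the noiseless limit it agrees with the closed
form (T − a)/(1 + b).

## Synthetic cohorts

The generator emulates the joint structure the analysis assumes; defaults
are the study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| D1 family | log-normal | positive, right-skewed, as organ-dose distributions are |
| D1 median / 66th pct | 5.3 / 5.6 Gy | pins the reference 66th percentile; the median (and hence σ_log ≈ 0.11) follows from the exceedance calibration below |
| D2 \| D1 | D1 + N(0, 0.5²) | cycles at fixed activity are near-replicates; this conditional is a modelling choice, not an estimated relation |
| D3, D4 conditionals | reference coefficients (0.37, 0.14, 0.83) and (0.99, 0.12, 0.19, 0.50) | the package's reference inter-cycle regressions serve as the generative truth |
| residual sds | 0.5 Gy (1.0 Gy for the joint D3+D4 form) | calibrated once so ≈ 13–14% of four-cycle completers exceed 25 Gy, the proportion typical of empiric four-cycle courses |
| dropout fractions | bone-marrow 5.2%, clinical deterioration 25%, salvage series 7.9%, other 6.9% | realistic non-kidney stop proportions for a referral-centre cohort |
| activity | 7.4 GBq per cycle | the empiric protocol |

Kidney-dose stops are *emergent*, not configured: the legacy extrapolation
rule is applied to the simulated doses before each of cycles 2–4, which
reproduces the mechanism by which such cohorts are censored in practice
(≈ 8% of a default cohort stops this way, almost always after cycle 3).
Non-kidney stops are dose-independent and truncate at a uniformly chosen
cycle 1–3. Doses are kept positive by re-drawing the residual (never
truncating, which would leave a point mass at zero); resampling is capped
at 100 attempts and errors beyond.

Sequential generation (D3 from its conditional, then D4) does not
guarantee that a refit of D3 + D4 on (D1, D2) recovers the joint-form
coefficients; the `joint_mode` flag generates D3 + D4 directly from the
joint form and splits it by a configurable fraction (default 0.5) for
exactly that test.

Each patient draws from an independent substream
(`SeedSequence(seed, spawn_key=(i,))`), so enlarging a cohort preserves
the patients already generated.

What the generator does *not* emulate: per-kidney vs mean-kidney dose
distinctions, administered-activity variation, correlation between dropout
reasons and dose (other than kidney stops), measurement error from the
imaging chain, or inter-centre calibration differences. Passing tests
therefore demonstrate the statistical machinery is correct under the
assumed model, not that the fitted coefficients transfer to any particular
clinic — coefficients of this kind are specific to the imaging and
dosimetry pipeline that produced them.

## Workload accounting

Empiric protocol: 3 scans after cycle 1, 1 after each later cycle, one
inpatient night per scanned cycle (the day-7 session after cycle 1 is
ambulatory). Predictive protocol: cycle 1 is always fully scanned; later
cycles are scanned only while the planner's previous action was
"continue with PTS"; unscanned cycles allow same-day release (0 nights by
default). A pre-release 15-minute planar scan is tallied separately and
not counted as a PTS. Counting rules are configurable because scan-session
and admission policies differ between centres; scanner-time figures
(35 min per PTS) are informational only.

## Problem sizes and numerical choices

Test fixtures use 4 000-patient no-dropout cohorts for stable fits,
10 000 patients for single-run coefficient recovery (within 3 standard
errors), 200 replicates of 90 patients for unbiasedness (within 2
Monte-Carlo standard errors of the replicate mean), 200 000 draws for the
Monte-Carlo check of the exceedance probability (agreement within 0.005),
and 1 000 replications at n = 100 for diagnostic type-I calibration
(nominal 5%, accepted band 3–7%). Cohort files round-trip exactly:
doses are written at 17 significant digits and parsed with round-trip
float precision.

## Known limitations

* The decision module consumes probabilities, not precomputed polygonal
  zones; this is exact at boundaries but means zone geometry exists only
  through the exported contour grids.
* The legacy rule and the predictive planner can disagree on a synthetic
  patient (the generator truncates by the legacy rule; the planner may
  have cleared or capped the same patient earlier). The workload counter
  deliberately scores the administered cycles, mirroring a retrospective
  projection.
* Bone-marrow dosimetry, eligibility, image acquisition and the absorbed
  dose computation itself are out of scope: doses enter this package as
  numbers in Gy.
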