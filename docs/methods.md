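# Methods

## Data model and scales

One analysed record is an adjusted standard-gamble (SG) valuation `y_ij ∈
[−1, 1]` of SF-6D state `s` by respondent `i` at card position `j` (1–6;
position 6 is always the pits state `645655`, the anchor the chained SG
design values against death). Death = 0, full health = 1; worse-than-death
responses are bounded below at −1. The package never simulates the
ping-pong elicitation itself — models only ever see adjusted values, so the
generator emits those directly.

## The four models

All models share the 25-dummy main-effect structure over the six dimensions
(levels above 1 only; level 1 is each dimension's baseline). M1 is pooled
OLS-style regression treating all 3518 valuations as independent; M2 adds a
respondent random effect `u_i`, splitting the residual into between-
(σ_u) and within-respondent (σ_e) parts; M3 fixes the intercept at unity so
the best state is modelled at exactly 1 (a QALY-scale requirement, not a
data-driven choice); M4 adds the `most` dummy — an interaction term
flagging states with any dimension at a most-severe level (PF 4–6, RL 3–4,
PAIN 5–6, SF/MH/VIT 4–5) — capturing an extra decrement for extreme
states.

The unity constraint is implemented as a response shift: fit `y − 1` with
no intercept column, so the modelled mean is `1 + Σ β_δλ x_δλ (+
β_most·most) + u_i`. A literal "no intercept" reading would anchor full
health at 0, which contradicts the constraint's purpose; the shift makes
`111111` predict exactly 1 with zero posterior spread, by construction.

Priors are vague and conjugate: every coefficient ~ N(0, 10⁶); every
precision (1/σ², and 1/σ_u², 1/σ_e² where present) ~ Gamma(0.001, 0.001).
The observation-level variance of the random-effects models is σ_e²; a
single σ symbol printed alongside both components in summaries refers to
that within-respondent scale.

## Gibbs sampler

All full conditionals are closed-form (multivariate normal for the
coefficient block, normal for each `u_i`, gamma for each precision), so the
sampler is a plain blocked Gibbs cycle — coefficients are drawn jointly per
sweep via a Cholesky solve rather than scalar-at-a-time, which mixes nearly
as well as independent sampling for these designs. Defaults mirror the
study conditions: 1000 burn-in sweeps, 10,000 kept sweeps, two parallel
chains. Chain c starts its coefficients at the over-dispersed offset ±d,
±2d, … (d = `dispersion`, default 1.0 — roughly 20× the typical decrement
size) with variances at 1 and `u` at 0.

Reproducibility: the master seed spawns one child stream per chain, and
each chain spawns one stream per conditional block (coefficients, random
effects, the two precisions), so changing one block's draw count never
scrambles the others. Convergence is the classic two-chain Gelman–Rubin
potential scale reduction factor, `sqrt(((k−1)/k·W + B/k)/W)`, computed per
monitored scalar (each coefficient and variance component) without
splitting or rank-normalisation; a fit is flagged converged when every
value is below the conventional 1.1. Degenerate constant chains report 1 by
convention with a warning. Non-converged runs are never dropped — the flag
travels with the draws.

## Synthetic survey generator

The generator emulates the UK study's structure; its defaults *are* those
study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_recruited` | 836 | interviewed respondents |
| `n_orthogonal` / `n_random` | 49 / 200 | design-state selection (249 total, pits always included) |
| `n_failed_pits` / `n_missing_two_plus` / `n_constant` | 130 / 9 / 86 | exclusion categories |
| `n_missing` | 148 | missing valuations among retained respondents |
| `beta`, `beta_most` | published posterior means | true decrements of the generating model (M4 form) |
| `sigma_e` | 0.219 | within-respondent SD (published) |
| `sigma_u` | 0.269 | between-respondent SD, derived as sqrt(0.347² − 0.219²) from the published pooled and within-respondent residual scales (it was never printed directly) |
| `truncate` | True | clip values to [−1, 1] |

Design selection: the "orthogonal" part is a balanced fractional set (each
dimension column is a shuffled cyclic fill of its levels, so every level
appears ≥ ⌊49/6⌋ times); the random part is stratified over mild (no
severe level, ≤ 2 dummies), severe (`most` = 1) and moderate (remainder)
states in near-equal thirds. Each respondent values five distinct non-pits
states — dealt greedily to the least-used states so replication stays
balanced (≈ 3055/248 ≈ 12 per state; replication is a consequence of the
cohort size and design size, not a separate dial) — plus the pits state at
position 6.

Values are `1 + x'β + β_most·most + u_i + e_ij` clipped to [−1, 1].
Worse-than-death values arise by truncation of the normal draw at −1
(the simplest bounded mechanism consistent with the scale), not
resampling. Exclusion-category behaviour is generated observably: flagged
respondents get a missing pits value, two missing design states, or five
identical design-state values respectively; flags are mutually exclusive.
Missingness is completely at random, one valuation for each of
`n_missing` distinct retained-eligible respondents — the real study's 148
missing clustered in 117 respondents, but a respondent with ≥ 2 missing
would be excluded by the filter, so the one-per-respondent scheme is the
only one that keeps the published provenance arithmetic exact. For the
same reason the generator redraws the noise of any unflagged respondent
whose five values coincide after clipping at 1.0 (a rare event), so the
constant-valuation rule fires exactly for flagged respondents.

The exclusion filter works on observed data only (it never reads generator
flags, so externally supplied CSVs filter identically), in the narrative
order: missing/absent pits valuation → two-plus missing valuations → five
identical observed design-state values (exact float equality; the rule
fires only when all five are present). A respondent matching several rules
counts under the first. Provenance (recruited / per-category exclusions /
retained / issued / missing / analysed) is attached to the filtered
dataset.

What the generator does **not** emulate: elicitation rounding to
probability grids, demographic covariates and cluster sampling,
respondent-level missingness clustering, and any non-normal or
heteroscedastic error. Because values are truncated, replica data are
*not* exactly from the linear-normal model class: mild states get clipped
at 1.0 often enough that fitted models over-predict some held-out mild
states. Tests that check calibration against the generating truth
therefore use `truncate=False` (model-class data); tests of the realistic
pipeline (provenance, skewness, negative-value share, model ordering) use
the truncated default. Passing tests show the machinery is correct under
these conditions — they cannot certify performance on the unreleased real
survey data.

## Evaluation choices

* **In-sample metrics** (R², adjusted R², mean |error|, RMSE) use
  posterior-mean coefficients. For random-effects models the predictions
  condition on the posterior-mean `u_i`, so the residual is the
  within-respondent error — this is the convention under which the
  published comparison's ≈ 0.68 vs ≈ 0.20 R² gap between the
  random-effects and pooled models is reproducible; with `u` forced to 0
  all four models would score alike. `include_random_effects=False` gives
  the population-level alternative, and `state_level=True` aggregates to
  per-state means first.
* **Adjusted R²** counts p as covariates excluding any intercept: 25 for
  M1–M3, 26 for M4. This convention reproduces the published adjusted
  values from the published R² column to 3 dp.
* **`predict_state`** is population-level (u = 0) and summarises the
  posterior of the state *mean* utility: mean, SD, central 95% credible
  interval over pooled kept draws.
* **Hold-out validation** removes every valuation of the held-out states
  and refits. The predictive distribution compared against a held-out
  state's observed sample mean includes the sampling noise of that mean:
  per posterior draw, variance (σ_u² + σ_e²)/n_s is added (σ_e²/n_s in
  respondent-conditional mode, where the valuing respondents' own `u_i`
  draws are averaged in instead — possible because those respondents keep
  their other valuations in the training set). With the default σ's and
  n_s ≈ 14 this predictive SD is ≈ 0.09; without the sampling component
  the standardized errors would be several units wide and no Q-Q check
  could succeed. Standardized errors use Q-Q plotting positions
  (k − 0.5)/m. Random hold-out selection never removes the pits state and
  re-draws if a removal would leave a dummy column with no supporting
  record.
* **Degenerate inputs** raise: R² on constant observations, adjusted R²
  with n ≤ p + 1, empty vectors, single-chain Gelman–Rubin, unvalued
  held-out states, designs containing missing values.

## Problem sizes used in checks

The shipped tests and the acceptance script run the full replica scale
(836 → 3518 records) but with shortened chains (typically 2 × 600–2000
kept after 200–500 burn-in): the blocked conjugate sampler mixes nearly
iid, so these short chains already give Monte-Carlo errors far below the
assertion tolerances, and R-hat sits at ≈ 1.002. The parameter-recovery
simulation uses 600 respondents × 6 valuations; the sampler-vs-quadrature
oracle uses 10 observations, 2 coefficients and 50,000 kept draws against
a 501² grid with the residual precision marginalised analytically.

## Known limitations

* The linear-normal likelihood ignores the bounded, skewed nature of SG
  values; Tobit/two-part/GLM alternatives are out of scope.
* σ_u's default is derived, not published; real between-respondent
  heterogeneity may differ.
* The frequentist REML comparator is not implemented (OLS appears only as
  a test oracle for M1); published frequentist columns are not reproduced.
* Exact reproduction of the published coefficient table and fit metrics is
  impossible without the unreleased survey data; the package reproduces
  their arithmetic and their qualitative structure on synthetic replicas.
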