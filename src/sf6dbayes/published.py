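"""Published summary results from the original UK SF-6D valuation study.

The raw valuation dataset from the UK survey (836 recruited respondents,
249 states valued by standard gamble) was never deposited publicly, but the
study's published summary tables are reusable inputs:

* the posterior-mean coefficients of the best-performing random-effects
  model (unity intercept + ``most`` interaction), used here as the default
  "true" parameters of the synthetic survey generator;
* the per-model goodness-of-fit column (R^2) of the model comparison;
* the 12-state out-of-sample prediction table (true sample mean, posterior
  predictive mean/SD), whose difference column feeds the published hold-out
  error summaries.

Values are transcribed at their printed precision.
"""

from __future__ import annotations

from .state_space import DUMMY_NAMES

__all__ = [
    "STUDY_COUNTS",
    "MODEL4_COEFFICIENTS",
    "MODEL4_BETA_MOST",
    "SIGMA_TOTAL_OLS",
    "SIGMA_E_RE",
    "SIGMA_U_DERIVED",
    "PUBLISHED_R2",
    "PUBLISHED_ADJ_R2",
    "MODEL_P",
    "HOLDOUT_TABLE",
]

#: Sample provenance of the UK study: recruited interviews, exclusions and
#: the analysed record count.
STUDY_COUNTS = {
    "usable_addresses": 1278,
    "recruited": 836,
    "excluded_failed_pits": 130,
    "excluded_missing_two_plus": 9,
    "excluded_constant": 86,
    "retained": 611,
    "valuations_issued": 3666,
    "missing_among_retained": 148,
    "analysed_valuations": 3518,
    "design_states": 249,
}

#: Posterior-mean level decrements of the unity-intercept random-effects
#: model with the ``most`` interaction, in canonical dummy order.
MODEL4_COEFFICIENTS = {
    "PF2": -0.050,
    "PF3": -0.039,
    "PF4": -0.069,
    "PF5": -0.046,
    "PF6": -0.146,
    "RL2": -0.051,
    "RL3": -0.058,
    "RL4": -0.063,
    "SF2": -0.053,
    "SF3": -0.032,
    "SF4": -0.043,
    "SF5": -0.095,
    "PAIN2": -0.037,
    "PAIN3": -0.034,
    "PAIN4": -0.040,
    "PAIN5": -0.081,
    "PAIN6": -0.167,
    "MH2": -0.036,
    "MH3": -0.046,
    "MH4": -0.100,
    "MH5": -0.116,
    "VIT2": -0.031,
    "VIT3": -0.018,
    "VIT4": -0.021,
    "VIT5": -0.072,
}
assert tuple(MODEL4_COEFFICIENTS) == DUMMY_NAMES

MODEL4_BETA_MOST = -0.083

#: Residual SD of the pooled (no random effect) regression.
SIGMA_TOTAL_OLS = 0.347
#: Within-respondent residual SD of the random-effects models.
SIGMA_E_RE = 0.219
#: Between-respondent SD implied by the two published residual scales
#: (sqrt(0.347^2 - 0.219^2)); the study never printed sigma_u itself.
SIGMA_U_DERIVED = 0.269

#: Published unadjusted R^2 per model on the analysed UK sample.
PUBLISHED_R2 = {"M1": 0.197, "M2": 0.679, "M3": 0.681, "M4": 0.683}
#: Published adjusted R^2 per model.
PUBLISHED_ADJ_R2 = {"M1": 0.191, "M2": 0.677, "M3": 0.679, "M4": 0.681}
#: Covariate count per model (intercept excluded; M4 adds ``most``).
MODEL_P = {"M1": 25, "M2": 25, "M3": 25, "M4": 26}

#: Out-of-sample prediction table for the 12 randomly held-out states:
#: state code -> (true sample mean, posterior predictive mean, SD).
#: The difference column of the published table is true - mean.
HOLDOUT_TABLE = {
    "112111": (0.8212, 0.8704, 0.0867),
    "133132": (0.5686, 0.7400, 0.0884),
    "223451": (0.6755, 0.5122, 0.0892),
    "235224": (0.4687, 0.6050, 0.0896),
    "241531": (0.7534, 0.6282, 0.0894),
    "325455": (0.4677, 0.4612, 0.0883),
    "332411": (0.7692, 0.7353, 0.0896),
    "333154": (0.6364, 0.6013, 0.0879),
    "421314": (0.7121, 0.7597, 0.0898),
    "423433": (0.5759, 0.6172, 0.0878),
    "545644": (0.2484, 0.3269, 0.0872),
    "621221": (0.4937, 0.6235, 0.0889),
}
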