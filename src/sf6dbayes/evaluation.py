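"""Fit metrics, posterior prediction and out-of-sample validation.

Model comparison uses the proportion of explained variance

    R^2 = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar)^2,

its adjustment for model size

    adjusted R^2 = 1 - (1 - R^2) * (n - 1) / (n - p - 1),

the mean absolute prediction error, and

    RMSE = sqrt( sum_i (y_i - yhat_i)^2 / n ).

``p`` counts covariate columns excluding any intercept: 25 for the pooled
and plain random-effects models, 26 once the ``most`` interaction enters.

Hold-out validation removes all valuations of a random set of states,
refits, and compares each held-out state's observed sample mean with its
posterior predictive distribution *for that sample mean*: per posterior
draw, the state's mean utility plus sampling noise with variance
(sigma_u^2 + sigma_e^2) / n_s for the n_s removed valuations (sigma_e^2
only in respondent-conditional mode, where the valuing respondents'
random-effect draws are used directly).  Standardized prediction errors
(true mean - predicted mean) / predictive SD are examined against N(0, 1)
via Q-Q coordinates with plotting positions (k - 0.5) / m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import gibbs
from .cohort import SurveyDataset
from .models import ModelSpec, build_design, get_spec
from .state_space import PITS, HealthState, dummy_vector, parse_state

__all__ = [
    "FitMetrics",
    "PredictionSummary",
    "HoldoutResult",
    "r_squared",
    "adjusted_r_squared",
    "rmse",
    "mean_abs_error",
    "predict_state",
    "select_holdout_states",
    "holdout_validate",
    "compare_models",
    "state_series",
    "qq_coordinates",
]


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def _paired(observed, predicted, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D vectors of equal length")
    if len(obs) < min_len:
        raise ValueError(f"need at least {min_len} paired values, got {len(obs)}")
    return obs, pred


def r_squared(observed, predicted) -> float:
    """Unadjusted R^2; negative when predictions do worse than the mean."""
    obs, pred = _paired(observed, predicted, 2)
    denom = float(((obs - obs.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValueError("observed values are all identical: R^2 is undefined")
    return 1.0 - float(((obs - pred) ** 2).sum()) / denom


def adjusted_r_squared(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 for n observations and p covariates."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 needs n > p + 1 (got n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rmse(observed, predicted) -> float:
    """Root-mean-square prediction error."""
    obs, pred = _paired(observed, predicted, 1)
    return float(np.sqrt(((obs - pred) ** 2).mean()))


def mean_abs_error(observed, predicted) -> float:
    """Mean absolute prediction error."""
    obs, pred = _paired(observed, predicted, 1)
    return float(np.abs(obs - pred).mean())


@dataclass
class FitMetrics:
    """Goodness-of-fit summary for one model."""

    model: str
    r2: float
    adjusted_r2: float
    mean_abs_error: float
    rmse: float
    n: int
    p: int


# ---------------------------------------------------------------------------
# posterior prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionSummary:
    """Posterior predictive summary of one state's mean utility."""

    state: HealthState
    draws: np.ndarray
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    true_mean: float | None = None
    n_observed: int | None = None

    @property
    def difference(self) -> float | None:
        """True sample mean minus predicted mean (None without data)."""
        if self.true_mean is None:
            return None
        return self.true_mean - self.mean


def _state_mean_draws(
    draws: gibbs.PosteriorDraws, state: HealthState, spec: ModelSpec
) -> np.ndarray:
    x = dummy_vector(state).as_array(include_most=spec.includes_most)
    if spec.has_intercept:
        x = np.concatenate([[1.0], x])
    return draws.offset + draws.pooled_coef() @ x


def predict_state(
    draws: gibbs.PosteriorDraws, state: HealthState | str, spec: ModelSpec | None = None
) -> PredictionSummary:
    """Posterior distribution of a state's population mean utility
    (respondent effect at its population mean of zero).

    Under the unity constraint (M3/M4) state 111111 yields every draw
    exactly 1 with zero spread.
    """
    if isinstance(state, str):
        state = parse_state(state)
    spec = draws.spec if spec is None else spec
    vals = _state_mean_draws(draws, state, spec)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return PredictionSummary(
        state=state,
        draws=vals,
        mean=float(vals.mean()),
        sd=sd,
        ci_low=float(lo),
        ci_high=float(hi),
    )


# ---------------------------------------------------------------------------
# hold-out validation
# ---------------------------------------------------------------------------

def qq_coordinates(standardized_errors) -> tuple[np.ndarray, np.ndarray]:
    """(theoretical N(0,1) quantiles, ordered errors) using plotting
    positions (k - 0.5) / m."""
    errs = np.sort(np.asarray(standardized_errors, dtype=float))
    m = len(errs)
    if m == 0:
        raise ValueError("no standardized errors supplied")
    theo = stats.norm.ppf((np.arange(1, m + 1) - 0.5) / m)
    return theo, errs


@dataclass
class HoldoutResult:
    """Out-of-sample validation output for a set of held-out states."""

    summaries: list[PredictionSummary]
    standardized_errors: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    n_training_states: int

    def table(self) -> pd.DataFrame:
        """Report with the published hold-out table's column layout."""
        return pd.DataFrame(
            {
                "state": [s.state.code for s in self.summaries],
                "true_sample_mean": [s.true_mean for s in self.summaries],
                "predicted_mean": [s.mean for s in self.summaries],
                "predicted_sd": [s.sd for s in self.summaries],
                "difference": [s.difference for s in self.summaries],
            }
        )

    def metrics(self) -> dict[str, float]:
        diff = np.array([s.difference for s in self.summaries])
        return {
            "rmse": float(np.sqrt((diff**2).mean())),
            "mean_abs_error": float(np.abs(diff).mean()),
        }


def select_holdout_states(
    dataset: SurveyDataset, n_holdout: int, seed=0
) -> list[HealthState]:
    """Randomly select states to hold out, never the pits state (the
    chaining anchor), and only such that every dummy column keeps at least
    one supporting record in the training data."""
    rng = np.random.default_rng(seed)
    observed = sorted(
        {r.state.code for r in dataset.records if r.value is not None} - {PITS}
    )
    if n_holdout > len(observed):
        raise ValueError("not enough valued states to hold out that many")
    for _ in range(1000):
        pick = set(rng.choice(observed, size=n_holdout, replace=False))
        rows = [
            dummy_vector(r.state).as_array(include_most=True)
            for r in dataset.records
            if r.value is not None and r.state.code not in pick
        ]
        if rows and np.array(rows).sum(axis=0).min() > 0:
            return [parse_state(c) for c in sorted(pick)]
    raise RuntimeError(
        "could not find a hold-out set leaving every dummy level represented"
    )


def holdout_validate(
    dataset: SurveyDataset,
    spec: ModelSpec | str,
    config: gibbs.SamplerConfig,
    held_out_states: list[HealthState],
    respondent_conditional: bool = False,
) -> HoldoutResult:
    """Remove every valuation of ``held_out_states``, refit, and predict each
    held-out state.

    The default compares state-level sample means with population-level
    predictions (u = 0).  With ``respondent_conditional=True`` the
    predictive draws are instead averaged over the posterior random-effect
    draws of exactly the respondents who valued the state — possible
    because those respondents keep their other valuations in the training
    set.
    """
    if not isinstance(spec, ModelSpec):
        spec = get_spec(spec)
    held_codes = {s.code if isinstance(s, HealthState) else str(s) for s in held_out_states}

    held_records: dict[str, list] = {c: [] for c in held_codes}
    training_records = []
    for rec in dataset.records:
        if rec.state.code in held_codes:
            if rec.value is not None:
                held_records[rec.state.code].append(rec)
        else:
            training_records.append(rec)
    empty = sorted(c for c, recs in held_records.items() if not recs)
    if empty:
        raise ValueError(f"held-out states with no observed valuations: {empty}")

    training = SurveyDataset(
        respondents=dataset.respondents,
        records=training_records,
        design_states=[s for s in dataset.design_states if s.code not in held_codes],
        provenance=dict(dataset.provenance),
    )
    if respondent_conditional and not config.store_u:
        raise ValueError("respondent-conditional prediction needs store_u=True")
    draws = gibbs.fit(training, spec, config)

    u_pool = draws.u.reshape(-1, draws.u.shape[2]) if draws.u is not None else None
    rid_index = {rid: j for j, rid in enumerate(draws.respondent_ids)}
    sigma_e2 = draws.sigma_e2.reshape(-1)
    sigma_u2 = (
        draws.sigma_u2.reshape(-1) if draws.sigma_u2 is not None else np.zeros_like(sigma_e2)
    )
    # dedicated stream for the predictive sampling noise, disjoint from the
    # chain streams spawned off the plain seed
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x486F6C64]))

    summaries = []
    for code in sorted(held_codes):
        recs = held_records[code]
        n_s = len(recs)
        mean_draws = _state_mean_draws(draws, parse_state(code), spec)
        if respondent_conditional and u_pool is not None:
            cols = [rid_index[r.respondent_id] for r in recs
                    if r.respondent_id in rid_index]
            if cols:
                mean_draws = mean_draws + u_pool[:, cols].mean(axis=1)
            sampling_var = sigma_e2 / n_s
        else:
            sampling_var = (sigma_u2 + sigma_e2) / n_s
        vals = mean_draws + rng.standard_normal(len(mean_draws)) * np.sqrt(sampling_var)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        summary = PredictionSummary(
            state=parse_state(code),
            draws=vals,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)),
            ci_low=float(lo),
            ci_high=float(hi),
            true_mean=float(np.mean([r.value for r in recs])),
            n_observed=n_s,
        )
        summaries.append(summary)

    std_errors = np.array(
        [s.difference / s.sd if s.sd > 0 else np.nan for s in summaries]
    )
    theo, ordered = qq_coordinates(std_errors[np.isfinite(std_errors)])
    n_training_states = len({r.state.code for r in training_records})
    return HoldoutResult(
        summaries=summaries,
        standardized_errors=std_errors,
        qq_theoretical=theo,
        qq_sample=ordered,
        n_training_states=n_training_states,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def _in_sample_predictions(
    design, draws: gibbs.PosteriorDraws, include_random_effects: bool
) -> np.ndarray:
    pred = design.offset + design.X @ draws.coef_mean()
    if include_random_effects and draws.spec.has_random_effects:
        u = draws.u_mean()
        if u is not None:
            pred = pred + u[design.respondent_index]
    return pred


def compare_models(
    dataset: SurveyDataset,
    specs,
    config: gibbs.SamplerConfig,
    include_random_effects: bool = True,
    state_level: bool = False,
) -> pd.DataFrame:
    """Fit each spec and tabulate R^2, adjusted R^2, mean absolute error
    and RMSE from posterior-mean parameters.

    In-sample predictions for random-effects models condition on the
    posterior-mean respondent effects by default (the residual then being
    the within-respondent error, as in the published comparison);
    ``include_random_effects=False`` gives population-level predictions
    instead.  ``state_level=True`` aggregates observed and predicted values
    to per-state means before computing the metrics.
    """
    if not specs:
        raise ValueError("need at least one model spec to compare")
    rows = []
    for spec in specs:
        if not isinstance(spec, ModelSpec):
            spec = get_spec(spec)
        design = build_design(dataset, spec)
        draws = gibbs.fit(dataset, spec, config)
        pred = _in_sample_predictions(design, draws, include_random_effects)
        obs = design.y + design.offset
        if state_level:
            codes = pd.Series([r.state.code for r in dataset.records])
            grouped = pd.DataFrame({"obs": obs, "pred": pred, "state": codes}).groupby(
                "state"
            )
            obs = grouped["obs"].mean().to_numpy()
            pred = grouped["pred"].mean().to_numpy()
        r2 = r_squared(obs, pred)
        rows.append(
            FitMetrics(
                model=spec.id,
                r2=r2,
                adjusted_r2=adjusted_r_squared(r2, design.n, design.p),
                mean_abs_error=mean_abs_error(obs, pred),
                rmse=rmse(obs, pred),
                n=design.n,
                p=design.p,
            )
        )
    return pd.DataFrame([vars(m) for m in rows]).set_index("model")


def state_series(
    dataset: SurveyDataset, draws: gibbs.PosteriorDraws
) -> pd.DataFrame:
    """Tidy per-state predicted-vs-actual series (ordered by predicted
    mean), suitable for plotting or CSV export."""
    df = pd.DataFrame(
        {
            "state": [r.state.code for r in dataset.records if r.value is not None],
            "value": [r.value for r in dataset.records if r.value is not None],
        }
    )
    grouped = df.groupby("state")["value"].agg(["mean", "count"])
    preds = {
        code: predict_state(draws, code).mean for code in grouped.index
    }
    out = pd.DataFrame(
        {
            "state": grouped.index,
            "n_observed": grouped["count"].to_numpy(),
            "observed_mean": grouped["mean"].to_numpy(),
            "predicted_mean": [preds[c] for c in grouped.index],
        }
    )
    out["error"] = out["observed_mean"] - out["predicted_mean"]
    return out.sort_values("predicted_mean").reset_index(drop=True)
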