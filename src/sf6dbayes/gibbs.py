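"""Multi-chain Gibbs fitting, convergence diagnostics and draw persistence.

The defaults mirror the original study's schedule: two parallel chains from broadly spread
initial values, 1000 burn-in iterations and 10,000 kept iterations, with
convergence assessed by the Gelman-Rubin potential scale reduction factor
(flagged converged when every monitored parameter is below 1.1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import _sampler
from .models import DesignData, ModelSpec, build_design, get_spec

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "run_chain",
    "gelman_rubin",
    "fit",
    "save_draws",
    "load_draws",
    "RHAT_THRESHOLD",
]

#: Conventional cutoff operationalising "convergence at about one".
RHAT_THRESHOLD = 1.1


@dataclass
class SamplerConfig:
    """Chain-length and seeding configuration for the Gibbs sampler."""

    n_burn: int = 1000
    n_keep: int = 10_000
    n_chains: int = 2
    seed: int = 0
    dispersion: float = 1.0
    thin: int = 1
    store_u: bool = True

    def validate(self) -> None:
        if self.n_burn < 0:
            raise ValueError("n_burn must be non-negative")
        if self.n_keep < 1:
            raise ValueError("n_keep must be at least 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be at least 1")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")


@dataclass
class PosteriorDraws:
    """Kept draws from all chains plus fit metadata.

    ``coef`` has shape (n_chains, n_kept, n_columns) with columns in
    canonical order (intercept first when present, then PF2..VIT5, then
    ``most``); ``sigma_u2`` and ``u`` are ``None`` for the pooled model.
    """

    coef: np.ndarray
    column_names: list[str]
    sigma_e2: np.ndarray
    sigma_u2: np.ndarray | None
    u: np.ndarray | None
    respondent_ids: list[str]
    spec: ModelSpec
    config: SamplerConfig
    offset: float
    rhat: dict[str, float] | None = None
    converged: bool | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.coef.shape[0]

    @property
    def n_kept(self) -> int:
        return self.coef.shape[1]

    def pooled_coef(self) -> np.ndarray:
        """Draws pooled over chains, shape (n_chains * n_kept, n_columns)."""
        return self.coef.reshape(-1, self.coef.shape[2])

    def coef_mean(self) -> np.ndarray:
        return self.pooled_coef().mean(axis=0)

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Per-chain draw matrices for every monitored scalar parameter."""
        out = {name: self.coef[:, :, j] for j, name in enumerate(self.column_names)}
        out["sigma_e2"] = self.sigma_e2
        if self.sigma_u2 is not None:
            out["sigma_u2"] = self.sigma_u2
        return out

    def u_mean(self) -> np.ndarray | None:
        if self.u is None:
            return None
        return self.u.reshape(-1, self.u.shape[2]).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """One row per kept iteration with a chain id column (respondent
        effects excluded)."""
        frames = []
        for ch in range(self.n_chains):
            df = pd.DataFrame(self.coef[ch], columns=self.column_names)
            df["sigma_e2"] = self.sigma_e2[ch]
            if self.sigma_u2 is not None:
                df["sigma_u2"] = self.sigma_u2[ch]
            df.insert(0, "iteration", np.arange(self.n_kept))
            df.insert(0, "chain", ch)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_chain(
    design: DesignData,
    spec: ModelSpec,
    config: SamplerConfig,
    chain_index: int,
    seed_sequence: np.random.SeedSequence | None = None,
) -> dict:
    """Run a single chain on a built design and return its raw draw arrays."""
    config.validate()
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(config.seed).spawn(config.n_chains)[
            chain_index
        ]
    return _sampler.run_gibbs_chain(
        design.y,
        design.X,
        design.respondent_index if spec.has_random_effects else None,
        coef_prior_variance=spec.coef_prior_variance,
        precision_prior_shape=spec.precision_prior_shape,
        precision_prior_rate=spec.precision_prior_rate,
        n_burn=config.n_burn,
        n_keep=config.n_keep,
        thin=config.thin,
        dispersion=config.dispersion,
        chain_index=chain_index,
        seed_sequence=seed_sequence,
        store_u=config.store_u,
    )


def _psrf(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  Constant chains return 1.0
    by convention (with a warning); chains with no within-chain variance
    but separated means return inf.
    """
    m, k = chains.shape
    within = chains.var(axis=1, ddof=1).mean()
    between_over_n = chains.mean(axis=1).var(ddof=1)
    if within == 0.0:
        if between_over_n == 0.0:
            warnings.warn(
                "degenerate (constant) chains: PSRF reported as 1 by convention",
                stacklevel=3,
            )
            return 1.0
        return np.inf
    var_plus = (k - 1) / k * within + between_over_n
    return float(np.sqrt(var_plus / within))


def gelman_rubin(draws: PosteriorDraws) -> dict[str, float]:
    """Gelman-Rubin statistic per monitored scalar parameter (coefficients
    and variance components), from between- and within-chain variances.
    Requires at least two chains."""
    if draws.n_chains < 2:
        raise ValueError(
            "the Gelman-Rubin diagnostic needs at least two chains; "
            "rerun with SamplerConfig(n_chains=2) or more"
        )
    return {name: _psrf(mat) for name, mat in draws.scalar_draws().items()}


def fit(dataset, spec, config: SamplerConfig | None = None) -> PosteriorDraws:
    """Fit a model to an exclusion-filtered dataset: build the design, run
    all chains, attach the convergence diagnostic (never silently dropping a
    non-converged run — the flag is recorded) and full metadata.

    Thin wrapper over :class:`sf6dbayes.estimator.BayesianUtilityRegressor`.
    """
    from .estimator import BayesianUtilityRegressor

    if not isinstance(spec, ModelSpec):
        spec = get_spec(spec)
    if config is None:
        config = SamplerConfig()
    config.validate()
    est = BayesianUtilityRegressor(
        model=spec.id,
        n_burn=config.n_burn,
        n_keep=config.n_keep,
        n_chains=config.n_chains,
        thin=config.thin,
        dispersion=config.dispersion,
        coef_prior_variance=spec.coef_prior_variance,
        store_u=config.store_u,
        random_state=config.seed,
    )
    est._fit_design(build_design(dataset, spec), config)
    return est.draws_


def save_draws(draws: PosteriorDraws, csv_path, meta_path=None) -> None:
    """Persist kept draws as CSV (chain id column, canonical parameter
    order) plus a JSON metadata sidecar; respondent effects are not
    persisted."""
    draws.to_frame().to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {
            "spec": draws.spec.metadata(),
            "config": asdict(draws.config),
            "offset": draws.offset,
            "column_names": draws.column_names,
            "rhat": draws.rhat,
            "converged": draws.converged,
        }
        meta.update(draws.metadata)
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)
            fh.write("\n")


def load_draws(csv_path, meta_path) -> PosteriorDraws:
    """Reload persisted draws for evaluation without refitting."""
    df = pd.read_csv(csv_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    spec = get_spec(meta["spec"]["id"])
    config = SamplerConfig(**meta["config"])
    names = meta["column_names"]
    chains = sorted(df["chain"].unique())
    coef = np.stack([df.loc[df["chain"] == ch, names].to_numpy() for ch in chains])
    sigma_e2 = np.stack(
        [df.loc[df["chain"] == ch, "sigma_e2"].to_numpy() for ch in chains]
    )
    sigma_u2 = None
    if "sigma_u2" in df.columns:
        sigma_u2 = np.stack(
            [df.loc[df["chain"] == ch, "sigma_u2"].to_numpy() for ch in chains]
        )
    return PosteriorDraws(
        coef=coef,
        column_names=list(names),
        sigma_e2=sigma_e2,
        sigma_u2=sigma_u2,
        u=None,
        respondent_ids=[],
        spec=spec,
        config=config,
        offset=float(meta["offset"]),
        rhat=meta.get("rhat"),
        converged=meta.get("converged"),
    )
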