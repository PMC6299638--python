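"""Scikit-learn style Bayesian regression estimator.

:class:`BayesianUtilityRegressor` is the package's central fitting object:
a linear (optionally random-effects) Gaussian regression with vague
conjugate priors, estimated by a blocked Gibbs sampler.  It follows the
sklearn estimator contract (``get_params``/``set_params``, ``fit`` /
``predict``, trailing-underscore fitted attributes) so it composes with
pipelines and model selection; the ``model`` parameter selects one of the
four valuation-model specifications (M1-M4), which govern intercept
handling, the unity constraint and random effects — not the column count,
so the estimator also fits arbitrary designs.

For the canonical SF-6D workflow, pass the 25-column dummy matrix (plus the
``most`` column for M4) as ``X``, the adjusted standard-gamble values as
``y`` and respondent identifiers as ``groups``; or use
:func:`sf6dbayes.gibbs.fit` to go straight from a survey dataset.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import _sampler
from .gibbs import (
    RHAT_THRESHOLD,
    PosteriorDraws,
    SamplerConfig,
    gelman_rubin,
)
from .models import DesignData, design_from_arrays, get_spec

__all__ = ["BayesianUtilityRegressor"]


class BayesianUtilityRegressor(RegressorMixin, BaseEstimator):
    """Bayesian (random-effects) linear regression fit by Gibbs sampling.

    Parameters
    ----------
    model : {"M1", "M2", "M3", "M4"}, default "M4"
        Specification: M1 pooled with intercept; M2 adds respondent random
        effects; M3/M4 fix the intercept at unity (response shifted by -1);
        M4 additionally expects the ``most`` interaction as the last column
        of ``X``.
    n_burn, n_keep, n_chains, thin
        Chain schedule: discarded burn-in sweeps, kept sweeps, number of
        parallel chains (two or more enable the Gelman-Rubin diagnostic),
        thinning interval.
    dispersion : float
        Scale of the over-dispersed chain-specific starting values for the
        coefficients (+d, -d, +2d, ... for successive chains).
    coef_prior_variance : float
        Prior variance of every regression coefficient (vague by default).
    store_u : bool
        Whether to keep per-iteration respondent-effect draws (needed for
        respondent-conditional prediction).
    random_state : int
        Master seed; chains and conditional blocks draw from deterministic
        child streams.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Posterior means of the covariate coefficients (intercept excluded).
    intercept_ : float
        Posterior-mean intercept for M1/M2; exactly 1.0 for M3/M4.
    sigma_e_, sigma_u_ : float
        Posterior means of the residual and respondent-effect SDs
        (``sigma_u_`` is ``None`` for M1).
    draws_ : PosteriorDraws
        Full per-chain draws with metadata.
    rhat_ : dict or None
        Gelman-Rubin statistic per parameter (None for a single chain).
    converged_ : bool or None
        True when every statistic is below 1.1.
    """

    def __init__(
        self,
        model: str = "M4",
        n_burn: int = 1000,
        n_keep: int = 10_000,
        n_chains: int = 2,
        thin: int = 1,
        dispersion: float = 1.0,
        coef_prior_variance: float = 1e6,
        store_u: bool = True,
        random_state: int = 0,
    ):
        self.model = model
        self.n_burn = n_burn
        self.n_keep = n_keep
        self.n_chains = n_chains
        self.thin = thin
        self.dispersion = dispersion
        self.coef_prior_variance = coef_prior_variance
        self.store_u = store_u
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self) -> SamplerConfig:
        config = SamplerConfig(
            n_burn=self.n_burn,
            n_keep=self.n_keep,
            n_chains=self.n_chains,
            seed=self.random_state,
            dispersion=self.dispersion,
            thin=self.thin,
            store_u=self.store_u,
        )
        config.validate()
        return config

    def _spec(self):
        spec = get_spec(self.model)
        if spec.coef_prior_variance != self.coef_prior_variance:
            from dataclasses import replace

            spec = replace(spec, coef_prior_variance=self.coef_prior_variance)
        return spec

    def fit(self, X, y, groups=None):
        """Fit the model to covariates ``X`` (intercept excluded), response
        ``y`` on the original value scale, and respondent labels ``groups``
        (required for the random-effects models M2-M4)."""
        spec = self._spec()
        if spec.has_random_effects and groups is None:
            raise ValueError(
                f"model {spec.id} has respondent random effects; pass groups="
            )
        design = design_from_arrays(X, y, groups, spec)
        return self._fit_design(design, self._config())

    def _fit_design(self, design: DesignData, config: SamplerConfig):
        """Fit from an already-built :class:`DesignData` (used by the
        dataset-level wrappers)."""
        spec = design.spec
        children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        chains = [
            _sampler.run_gibbs_chain(
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
                chain_index=ci,
                seed_sequence=children[ci],
                store_u=config.store_u,
            )
            for ci in range(config.n_chains)
        ]

        draws = PosteriorDraws(
            coef=np.stack([c["coef"] for c in chains]),
            column_names=list(design.column_names),
            sigma_e2=np.stack([c["sigma_e2"] for c in chains]),
            sigma_u2=(
                np.stack([c["sigma_u2"] for c in chains])
                if spec.has_random_effects
                else None
            ),
            u=(
                np.stack([c["u"] for c in chains])
                if spec.has_random_effects and config.store_u
                else None
            ),
            respondent_ids=list(design.respondent_ids),
            spec=spec,
            config=config,
            offset=design.offset,
            metadata={"n": design.n, "p": design.p},
        )
        if config.n_chains >= 2:
            draws.rhat = gelman_rubin(draws)
            draws.converged = all(v < RHAT_THRESHOLD for v in draws.rhat.values())

        self.draws_ = draws
        self.design_ = design
        coef_mean = draws.coef_mean()
        if spec.has_intercept:
            self.intercept_ = float(coef_mean[0])
            self.coef_ = coef_mean[1:]
        else:
            self.intercept_ = design.offset  # 1.0 under the unity constraint
            self.coef_ = coef_mean
        self.sigma_e_ = float(np.sqrt(draws.sigma_e2).mean())
        self.sigma_u_ = (
            float(np.sqrt(draws.sigma_u2).mean()) if spec.has_random_effects else None
        )
        self.random_effects_ = draws.u_mean()
        self.respondent_ids_ = list(design.respondent_ids)
        self.rhat_ = draws.rhat
        self.converged_ = draws.converged
        self.n_features_in_ = design.p
        return self

    # ------------------------------------------------------------------
    def predict(self, X, groups=None):
        """Population-level posterior-mean prediction on the original value
        scale.  When ``groups`` is given, posterior-mean respondent effects
        are added for labels seen during fitting (unknown labels predict at
        the population level)."""
        if not hasattr(self, "draws_"):
            raise AttributeError("estimator is not fitted yet")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} columns, got {X.shape}"
            )
        pred = self.intercept_ + X @ self.coef_
        if groups is not None and self.random_effects_ is not None:
            lookup = {rid: j for j, rid in enumerate(self.respondent_ids_)}
            for i, label in enumerate(np.asarray(groups)):
                j = lookup.get(str(label))
                if j is not None:
                    pred[i] += self.random_effects_[j]
        return pred
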