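"""Conjugate Gibbs sampler core.

For y = X b + Z u + e with e ~ N(0, 1/tau_e), u_i ~ N(0, 1/tau_u),
b_k ~ N(0, v0) and Gamma(a, c) priors on each precision, every full
conditional is available in closed form:

* b | .  ~  MVN(A^{-1} m, A^{-1}) with A = tau_e X'X + I/v0 and
  m = tau_e X'(y - Zu)  (single blocked draw per sweep);
* u_i | .  ~  N(tau_e s_i / d_i, 1/d_i) with d_i = tau_u + n_i tau_e and
  s_i the sum of that respondent's residuals y_ij - x_ij'b;
* tau_u | .  ~  Gamma(a + R/2, c + sum_i u_i^2 / 2);
* tau_e | .  ~  Gamma(a + n/2, c + SSE/2).

Chains start from over-dispersed values: coefficients at a chain-specific
offset of +/- dispersion, variances at 1, random effects at 0.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

__all__ = ["run_gibbs_chain", "chain_offset"]


def chain_offset(chain_index: int, dispersion: float) -> float:
    """Deterministic over-dispersed starting offset for a chain:
    +d, -d, +2d, -2d, ... for chains 0, 1, 2, 3, ..."""
    magnitude = 1 + chain_index // 2
    sign = 1.0 if chain_index % 2 == 0 else -1.0
    return sign * magnitude * dispersion


def run_gibbs_chain(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray | None,
    *,
    coef_prior_variance: float,
    precision_prior_shape: float,
    precision_prior_rate: float,
    n_burn: int,
    n_keep: int,
    thin: int = 1,
    dispersion: float = 1.0,
    chain_index: int = 0,
    seed_sequence: np.random.SeedSequence | None = None,
    store_u: bool = True,
) -> dict:
    """Run one chain and return kept draws.

    ``groups`` is a dense 0..R-1 respondent index, or ``None`` for the
    pooled model (no random effects).  Draw streams are spawned per
    conditional block from ``seed_sequence`` so the block updates stay
    reproducible independently of one another.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be at least 1")
    if n_burn < 0 or thin < 1:
        raise ValueError("n_burn must be >= 0 and thin >= 1")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("sampler inputs must be finite")
    n, k = X.shape
    a = precision_prior_shape
    c = precision_prior_rate

    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(0)
    rng_beta, rng_u, rng_tau_u, rng_tau_e = (
        np.random.default_rng(s) for s in seed_sequence.spawn(4)
    )

    random_effects = groups is not None
    if random_effects:
        groups = np.asarray(groups, dtype=np.intp)
        n_groups = int(groups.max()) + 1
        group_sizes = np.bincount(groups, minlength=n_groups).astype(float)
    else:
        n_groups = 0

    XtX = X.T @ X
    prior_prec = np.eye(k) / coef_prior_variance

    beta = np.full(k, chain_offset(chain_index, dispersion))
    u = np.zeros(n_groups)
    tau_e = 1.0
    tau_u = 1.0

    n_kept = n_keep // thin
    out_beta = np.empty((n_kept, k))
    out_sigma_e2 = np.empty(n_kept)
    out_sigma_u2 = np.empty(n_kept) if random_effects else None
    out_u = np.empty((n_kept, n_groups)) if (random_effects and store_u) else None

    kept = 0
    for it in range(n_burn + n_keep):
        # coefficient block
        r = y - u[groups] if random_effects else y
        A = tau_e * XtX + prior_prec
        try:
            L = linalg.cholesky(A, lower=True)
        except linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
            raise np.linalg.LinAlgError(
                "singular coefficient conditional covariance; the design is "
                "collinear — drop redundant columns or add observations"
            ) from exc
        mean = linalg.cho_solve((L, True), tau_e * (X.T @ r))
        z = rng_beta.standard_normal(k)
        beta = mean + linalg.solve_triangular(L, z, lower=True, trans="T")

        resid = y - X @ beta

        if random_effects:
            s = np.bincount(groups, weights=resid, minlength=n_groups)
            d = tau_u + group_sizes * tau_e
            u = tau_e * s / d + rng_u.standard_normal(n_groups) / np.sqrt(d)
            tau_u = rng_tau_u.gamma(a + n_groups / 2.0, 1.0 / (c + 0.5 * u @ u))
            err = resid - u[groups]
        else:
            err = resid

        tau_e = rng_tau_e.gamma(a + n / 2.0, 1.0 / (c + 0.5 * err @ err))

        j = it - n_burn
        if j >= 0 and j % thin == 0 and kept < n_kept:
            out_beta[kept] = beta
            out_sigma_e2[kept] = 1.0 / tau_e
            if out_sigma_u2 is not None:
                out_sigma_u2[kept] = 1.0 / tau_u
            if out_u is not None:
                out_u[kept] = u
            kept += 1

    return {
        "coef": out_beta,
        "sigma_e2": out_sigma_e2,
        "sigma_u2": out_sigma_u2,
        "u": out_u,
    }
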