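"""Optional matplotlib figures: predicted-vs-actual state series and the
Q-Q plot of standardized hold-out prediction errors."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

__all__ = ["plot_state_series", "plot_qq"]


def plot_state_series(series, path) -> None:
    """Predicted (solid) and observed (dotted) mean state values, states
    ordered by predicted value, with their difference as a dashed line."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    x = range(len(series))
    ax.plot(x, series["predicted_mean"], "-", lw=1.2, label="predicted mean")
    ax.plot(x, series["observed_mean"], ":", lw=1.0, label="observed mean")
    ax.plot(x, series["error"], "--", lw=0.8, label="error (obs - pred)")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("health states ordered by predicted value")
    ax.set_ylabel("mean adjusted SG value")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_qq(result, path) -> None:
    """Q-Q plot of standardized hold-out errors against N(0, 1)."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(result.qq_theoretical, result.qq_sample, "o", ms=5)
    lims = [
        min(result.qq_theoretical.min(), result.qq_sample.min()) - 0.3,
        max(result.qq_theoretical.max(), result.qq_sample.max()) + 0.3,
    ]
    ax.plot(lims, lims, "-", color="grey", lw=1.0)
    ax.set_xlabel("theoretical N(0,1) quantiles")
    ax.set_ylabel("standardized prediction errors")
    ax.set_xlim(lims)
    ax.set_ylim(lims)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
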