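"""Model specifications and design construction.

Four regression models for adjusted standard-gamble values:

* **M1** — pooled linear regression, y_i = b0 + sum_k b_k x_ki + eps_i,
  treating the ~6 valuations per respondent as independent;
* **M2** — random-effects model adding a respondent effect u_i, splitting
  the error into between- (sigma_u) and within-respondent (sigma_e) parts;
* **M3** — M2 with the intercept forced to unity, so full health (111111)
  is modelled at exactly 1 as the QALY scale requires;
* **M4** — M3 plus the ``most`` interaction dummy for states containing
  any dimension at a most-severe level.

Priors are deliberately vague: N(0, 1e6) on every regression coefficient
and Gamma(0.001, 0.001) on each precision (1/sigma^2).

The unity-intercept constraint is implemented by shifting the response to
y - 1 and fitting without an intercept column, so the modelled mean is
1 + sum_k b_k x_k (+ b_most * most) and state 111111 predicts exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import SurveyDataset
from .state_space import DUMMY_NAMES, dummy_vector

__all__ = ["ModelSpec", "DesignData", "MODEL_IDS", "get_spec", "build_design",
           "design_from_arrays"]

MODEL_IDS = ("M1", "M2", "M3", "M4")


@dataclass(frozen=True)
class ModelSpec:
    """One of the four model specifications (see module docstring)."""

    id: str
    has_intercept: bool
    intercept_fixed_at_unity: bool
    has_random_effects: bool
    includes_most: bool
    coef_prior_variance: float = 1e6
    precision_prior_shape: float = 0.001
    precision_prior_rate: float = 0.001

    def metadata(self) -> dict:
        return {
            "id": self.id,
            "has_intercept": self.has_intercept,
            "intercept_fixed_at_unity": self.intercept_fixed_at_unity,
            "has_random_effects": self.has_random_effects,
            "includes_most": self.includes_most,
            "coef_prior": f"Normal(0, {self.coef_prior_variance:g})",
            "precision_prior": (
                f"Gamma({self.precision_prior_shape:g}, "
                f"{self.precision_prior_rate:g})"
            ),
        }


_SPECS = {
    "M1": ModelSpec("M1", True, False, False, False),
    "M2": ModelSpec("M2", True, False, True, False),
    "M3": ModelSpec("M3", False, True, True, False),
    "M4": ModelSpec("M4", False, True, True, True),
}


def get_spec(model_id: str) -> ModelSpec:
    """Return the :class:`ModelSpec` for an id in {M1, M2, M3, M4}."""
    try:
        return _SPECS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model id {model_id!r}; expected one of {MODEL_IDS}"
        ) from None


@dataclass
class DesignData:
    """Response and covariates ready for the sampler.

    ``X`` holds the covariate columns in canonical dummy order (plus
    ``most`` for M4), with a leading intercept column for M1/M2.  ``y`` is
    the analysed response, shifted by -1 under the unity-intercept
    constraint; ``offset`` (0 or 1) restores the original scale.  ``p``
    counts covariate columns excluding any intercept.
    """

    y: np.ndarray
    X: np.ndarray
    column_names: list[str]
    respondent_index: np.ndarray
    respondent_ids: list[str]
    offset: float
    spec: ModelSpec = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1] - (1 if self.spec.has_intercept else 0)

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)


def design_from_arrays(
    X: np.ndarray,
    y: np.ndarray,
    groups,
    spec: ModelSpec,
    column_names: list[str] | None = None,
) -> DesignData:
    """Assemble a :class:`DesignData` from raw covariates (intercept
    excluded) and an untransformed response; ``groups`` are respondent
    labels (any hashable), densified to 0..R-1 in sorted-label order."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per response value")
    if len(y) == 0:
        raise ValueError("empty design: no analysed valuations")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("design inputs must be finite")

    if column_names is None:
        column_names = [f"x{j}" for j in range(X.shape[1])]
    column_names = list(column_names)

    if groups is None:
        groups = np.arange(len(y))
    labels = np.asarray(groups)
    if len(labels) != len(y):
        raise ValueError("groups must align with the response vector")
    unique, index = np.unique(labels, return_inverse=True)

    if spec.intercept_fixed_at_unity:
        y_work, offset = y - 1.0, 1.0
    else:
        y_work, offset = y.copy(), 0.0
    if spec.has_intercept:
        X = np.hstack([np.ones((len(y), 1)), X])
        column_names = ["intercept"] + column_names

    return DesignData(
        y=y_work,
        X=X,
        column_names=column_names,
        respondent_index=index.astype(np.intp),
        respondent_ids=[str(label) for label in unique],
        offset=offset,
        spec=spec,
    )


def build_design(dataset: SurveyDataset, spec: ModelSpec) -> DesignData:
    """Build the design for ``spec`` from an exclusion-filtered dataset.

    Rows follow the dataset's record order; records with a missing value are
    rejected (run the exclusion pipeline first).  Covariates are the 25
    level dummies, plus the ``most`` column for M4; p is therefore 25 for
    M1-M3 and 26 for M4.
    """
    if not isinstance(spec, ModelSpec):
        spec = get_spec(spec)
    if not dataset.records:
        raise ValueError("dataset has no valuation records")
    if any(rec.value is None for rec in dataset.records):
        raise ValueError(
            "dataset contains missing values; apply_exclusions must run first"
        )
    rows = [dummy_vector(rec.state).as_array(include_most=spec.includes_most)
            for rec in dataset.records]
    names = list(DUMMY_NAMES) + (["most"] if spec.includes_most else [])
    y = np.array([rec.value for rec in dataset.records], dtype=float)
    groups = [rec.respondent_id for rec in dataset.records]
    return design_from_arrays(np.array(rows), y, groups, spec, column_names=names)
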