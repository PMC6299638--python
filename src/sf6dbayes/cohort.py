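"""Synthetic standard-gamble valuation surveys.

The UK SF-6D valuation survey interviewed 836 members of the general
population; each respondent ranked and valued six health states by a
chained standard gamble (five design states plus the "pits" state 645655
as the sixth valuation), producing adjusted values on the death = 0 /
full-health = 1 scale, bounded below at -1 for states judged worse than
death.  The raw dataset is not public, so this module generates surveys
with the same structure and statistical character: a 249-state design
(balanced fractional part plus stratified-random part), respondent-level
random effects, left-skewed bounded values, partial missingness, and the
three respondent-exclusion categories applied during the original
analysis (failed pits valuation, two-plus missing states, constant
valuations).

The generator emits *adjusted* values directly — the chained elicitation
itself is not simulated mechanistically, since the regression models only
ever see the adjusted dependent variable.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import published
from .state_space import (
    DUMMY_NAMES,
    PITS,
    HealthState,
    dummy_vector,
    enumerate_states,
    parse_state,
)

__all__ = [
    "Respondent",
    "ValuationRecord",
    "SurveyDataset",
    "CohortConfig",
    "select_design_states",
    "generate_survey",
    "apply_exclusions",
    "response_rate_percent",
    "write_valuations",
    "read_valuations",
    "write_provenance",
]

#: Exclusion categories, in the order the filtering pipeline applies them.
EXCLUSION_CATEGORIES = ("failed_pits", "missing_two_plus", "constant_valuations")

N_VALUATIONS = 6  # five design states plus the pits valuation
PITS_POSITION = 6


class CohortConfigError(ValueError):
    """Raised for an infeasible cohort configuration."""


@dataclass
class Respondent:
    """One survey respondent with an optional generator-assigned exclusion flag."""

    id: str
    random_effect: float = 0.0
    flag: str | None = None


@dataclass
class ValuationRecord:
    """One adjusted standard-gamble observation (``value`` is ``None`` when missing)."""

    respondent_id: str
    state: HealthState
    value: float | None
    position: int


@dataclass
class SurveyDataset:
    """A valuation survey: respondents, records, the state design and provenance counts."""

    respondents: list[Respondent]
    records: list[ValuationRecord]
    design_states: list[HealthState]
    provenance: dict = field(default_factory=dict)

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    def records_by_respondent(self) -> dict[str, list[ValuationRecord]]:
        out: dict[str, list[ValuationRecord]] = {r.id: [] for r in self.respondents}
        for rec in self.records:
            out.setdefault(rec.respondent_id, []).append(rec)
        return out

    def observed_values(self) -> np.ndarray:
        return np.array([r.value for r in self.records if r.value is not None])


@dataclass
class CohortConfig:
    """Study conditions for the synthetic survey.

    Defaults reproduce the UK study's structure: 836 recruited respondents,
    a 249-state design (49 balanced + 200 stratified random), exclusion
    counts 130/9/86, 148 missing valuations among retained respondents, and
    true parameters set to the published posterior means of the best
    random-effects model, with sigma_e = 0.219 (within respondent) and
    sigma_u = 0.269 (between respondents, derived from the published total
    and within-respondent residual scales).
    """

    n_recruited: int = 836
    n_orthogonal: int = 49
    n_random: int = 200
    n_failed_pits: int = 130
    n_missing_two_plus: int = 9
    n_constant: int = 86
    n_missing: int = 148
    beta: dict[str, float] = field(
        default_factory=lambda: dict(published.MODEL4_COEFFICIENTS)
    )
    beta_most: float = published.MODEL4_BETA_MOST
    sigma_u: float = published.SIGMA_U_DERIVED
    sigma_e: float = published.SIGMA_E_RE
    truncate: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_recruited",
            "n_orthogonal",
            "n_random",
            "n_failed_pits",
            "n_missing_two_plus",
            "n_constant",
            "n_missing",
        ):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be non-negative")
        n_excluded = self.n_failed_pits + self.n_missing_two_plus + self.n_constant
        if n_excluded > self.n_recruited:
            raise CohortConfigError(
                f"exclusion counts sum to {n_excluded} > n_recruited={self.n_recruited}"
            )
        if self.n_missing > self.n_recruited - n_excluded:
            raise CohortConfigError(
                "n_missing exceeds the number of retained-eligible respondents "
                "(at most one injected missing valuation per retained respondent)"
            )
        if set(self.beta) != set(DUMMY_NAMES):
            raise CohortConfigError("beta must supply one value per dummy term")
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise CohortConfigError("noise scales must be non-negative")

    @property
    def n_retained(self) -> int:
        return self.n_recruited - (
            self.n_failed_pits + self.n_missing_two_plus + self.n_constant
        )


# ---------------------------------------------------------------------------
# design-state selection
# ---------------------------------------------------------------------------

def _severity_stratum(state: HealthState) -> str:
    """Mild = no most-severe level and at most 2 levels above baseline;
    severe = any most-severe level; moderate = the remainder."""
    dv = dummy_vector(state)
    if dv.most:
        return "severe"
    if sum(dv.values) <= 2:
        return "mild"
    return "moderate"


def select_design_states(
    n_orthogonal: int = 49, n_random: int = 200, seed=0
) -> list[HealthState]:
    """Select the valuation design: a balanced fractional part in which every
    dimension level appears, plus stratified-random states balanced across
    mild/moderate/severe strata.  The pits state is always included and the
    returned list is deduplicated (``n_orthogonal + n_random`` distinct
    states, or the pits state alone when both counts are zero).
    """
    from .state_space import DIMENSION_LEVELS

    rng = np.random.default_rng(seed)
    if n_orthogonal < 0 or n_random < 0:
        raise CohortConfigError("state counts must be non-negative")
    n_total = n_orthogonal + n_random
    if n_total > len(enumerate_states()):
        raise CohortConfigError("requested more states than the system defines")
    if 0 < n_orthogonal < max(DIMENSION_LEVELS):
        raise CohortConfigError(
            "the balanced fractional part needs at least "
            f"{max(DIMENSION_LEVELS)} states to cover every dimension level"
        )
    if n_total == 0:
        return [parse_state(PITS)]

    # Balanced fractional part: each dimension column is a shuffled cyclic
    # fill of its levels, so every level appears at least
    # floor(n_orthogonal / n_levels) times; regenerate on the (rare) row
    # collision so states stay distinct.
    selected: list[HealthState] = []
    if n_orthogonal:
        while True:
            cols = []
            for nmax in DIMENSION_LEVELS:
                col = np.tile(np.arange(1, nmax + 1), math.ceil(n_orthogonal / nmax))
                col = col[:n_orthogonal]
                rng.shuffle(col)
                cols.append(col)
            rows = {tuple(int(c[i]) for c in cols) for i in range(n_orthogonal)}
            if len(rows) == n_orthogonal:
                selected = [HealthState(r) for r in sorted(rows)]
                break

    # Stratified-random part, balanced across severity strata.
    if n_random:
        chosen = {s.code for s in selected}
        strata: dict[str, list[HealthState]] = {"mild": [], "moderate": [], "severe": []}
        for st in enumerate_states():
            if st.code not in chosen:
                strata[_severity_stratum(st)].append(st)
        base, rem = divmod(n_random, 3)
        quota = {
            name: base + (1 if i < rem else 0)
            for i, name in enumerate(("mild", "moderate", "severe"))
        }
        for name, k in quota.items():
            pool = strata[name]
            if k > len(pool):
                raise CohortConfigError(f"stratum {name!r} has only {len(pool)} states")
            idx = rng.choice(len(pool), size=k, replace=False)
            selected.extend(pool[i] for i in sorted(idx))

    codes = [s.code for s in selected]
    if PITS not in codes:
        # swap a random state (from the random part when available) for pits
        lo = len(codes) - n_random if n_random else 0
        drop = int(rng.integers(lo, len(codes)))
        selected[drop] = parse_state(PITS)
    return selected


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------

def _state_mean_utility(state: HealthState, config: CohortConfig) -> float:
    """Population mean value under the generating model: unity intercept plus
    level decrements plus the most-severe interaction."""
    dv = dummy_vector(state)
    beta = np.array([config.beta[name] for name in DUMMY_NAMES])
    return 1.0 + float(dv.as_array() @ beta) + config.beta_most * dv.most


def _maybe_truncate(values: np.ndarray, config: CohortConfig) -> np.ndarray:
    return np.clip(values, -1.0, 1.0) if config.truncate else values


def generate_survey(config: CohortConfig) -> SurveyDataset:
    """Simulate a full valuation survey under ``config``.

    Each retained-eligible respondent i receives a random effect
    u_i ~ N(0, sigma_u^2) shared across their six valuations; each value is
    the state's mean utility plus u_i plus e_ij ~ N(0, sigma_e^2), truncated
    to [-1, 1].  Respondents carrying an exclusion flag get the matching
    observable behaviour (missing pits value; two missing design states;
    five identical design-state values), and ``n_missing`` single missing
    valuations are injected completely at random among retained-eligible
    respondents.  Deterministic given ``config.seed``.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    ss_design, ss_flags, ss_u, ss_assign, ss_noise, ss_missing = master.spawn(6)

    design = select_design_states(config.n_orthogonal, config.n_random, seed=ss_design)
    nonpits = [s for s in design if s.code != PITS]
    pits = parse_state(PITS)
    if len(nonpits) < N_VALUATIONS - 1:
        raise CohortConfigError(
            "design must contain at least five non-pits states to fill a card set"
        )

    n = config.n_recruited
    width = max(4, len(str(n)))
    respondents = [Respondent(id=f"R{i + 1:0{width}d}") for i in range(n)]

    rng_flags = np.random.default_rng(ss_flags)
    order = rng_flags.permutation(n)
    cuts = np.cumsum([config.n_failed_pits, config.n_missing_two_plus, config.n_constant])
    for cat, lo, hi in zip(EXCLUSION_CATEGORIES, np.r_[0, cuts[:-1]], cuts):
        for i in order[lo:hi]:
            respondents[i].flag = cat

    rng_u = np.random.default_rng(ss_u)
    u = rng_u.normal(0.0, config.sigma_u, size=n)
    for r, ui in zip(respondents, u):
        r.random_effect = float(ui)

    # Deal five distinct non-pits states per respondent, preferring the
    # least-used states so replication is balanced across the design.
    rng_assign = np.random.default_rng(ss_assign)
    counts = np.zeros(len(nonpits))
    assignments: list[list[HealthState]] = []
    for _ in range(n):
        pick = np.lexsort((rng_assign.random(len(nonpits)), counts))[: N_VALUATIONS - 1]
        counts[pick] += 1
        assignments.append([nonpits[j] for j in pick])

    mu_cache = {s.code: _state_mean_utility(s, config) for s in design}
    rng_noise = np.random.default_rng(ss_noise)

    def draw_values(states: list[HealthState], ui: float) -> np.ndarray:
        mu = np.array([mu_cache[s.code] for s in states])
        e = rng_noise.normal(0.0, config.sigma_e, size=len(states))
        return _maybe_truncate(mu + ui + e, config)

    records: list[ValuationRecord] = []
    for resp, states in zip(respondents, assignments):
        cards = states + [pits]
        vals = draw_values(cards, resp.random_effect)
        if resp.flag == "constant_valuations":
            vals[: N_VALUATIONS - 1] = vals[0]
        elif resp.flag is None:
            # truncation at 1.0 can (rarely) make all five design values
            # coincide; redraw so the constant-valuation rule fires only for
            # flagged respondents and provenance arithmetic stays exact
            tries = 0
            while len(set(vals[: N_VALUATIONS - 1])) == 1:
                vals = draw_values(cards, resp.random_effect)
                tries += 1
                if tries > 1000:  # pragma: no cover - defensive
                    raise RuntimeError("could not draw non-constant valuations")
        for pos, (state, val) in enumerate(zip(cards, vals), start=1):
            records.append(ValuationRecord(resp.id, state, float(val), pos))

    by_resp = {r.id: [] for r in respondents}
    for rec in records:
        by_resp[rec.respondent_id].append(rec)

    rng_missing = np.random.default_rng(ss_missing)
    for resp in respondents:
        recs = by_resp[resp.id]
        if resp.flag == "failed_pits":
            recs[PITS_POSITION - 1].value = None
        elif resp.flag == "missing_two_plus":
            for j in rng_missing.choice(N_VALUATIONS - 1, size=2, replace=False):
                recs[j].value = None

    eligible = [r.id for r in respondents if r.flag is None]
    hit = rng_missing.choice(len(eligible), size=config.n_missing, replace=False)
    for i in sorted(hit):
        recs = by_resp[eligible[i]]
        j = int(rng_missing.integers(N_VALUATIONS - 1))
        recs[j].value = None

    return SurveyDataset(
        respondents=respondents,
        records=records,
        design_states=design,
        provenance={"recruited": n, "design_states": len(design)},
    )


# ---------------------------------------------------------------------------
# exclusion pipeline
# ---------------------------------------------------------------------------

def apply_exclusions(dataset: SurveyDataset) -> SurveyDataset:
    """Apply the analysis filters to *observed* data, in order: respondents
    with a missing (or absent) pits valuation; respondents missing two or
    more valuations; respondents whose five design-state values are all
    identical.  A respondent matching several rules is counted under the
    first.  Remaining missing records of retained respondents are dropped
    and full provenance counts are attached.
    """
    by_resp = dataset.records_by_respondent()
    excluded = dict.fromkeys(EXCLUSION_CATEGORIES, 0)
    retained: list[Respondent] = []
    kept_records: list[ValuationRecord] = []
    n_issued = 0
    n_missing_retained = 0

    for resp in dataset.respondents:
        recs = by_resp.get(resp.id, [])
        pits_recs = [r for r in recs if r.position == PITS_POSITION]
        nonpits = [r for r in recs if r.position != PITS_POSITION]
        n_missing = sum(r.value is None for r in recs) + (N_VALUATIONS - len(recs))
        if not pits_recs or pits_recs[0].value is None:
            excluded["failed_pits"] += 1
            continue
        if n_missing >= 2:
            excluded["missing_two_plus"] += 1
            continue
        values = [r.value for r in nonpits]
        if (
            len(values) == N_VALUATIONS - 1
            and all(v is not None for v in values)
            and len(set(values)) == 1
        ):
            excluded["constant_valuations"] += 1
            continue
        retained.append(resp)
        n_issued += len(recs)
        n_missing_retained += sum(r.value is None for r in recs)
        kept_records.extend(r for r in recs if r.value is not None)

    provenance = dict(dataset.provenance)
    provenance.update(
        recruited=len(dataset.respondents),
        excluded_failed_pits=excluded["failed_pits"],
        excluded_missing_two_plus=excluded["missing_two_plus"],
        excluded_constant=excluded["constant_valuations"],
        retained=len(retained),
        valuations_issued=n_issued,
        missing_among_retained=n_missing_retained,
        analysed_valuations=len(kept_records),
    )
    return SurveyDataset(
        respondents=retained,
        records=kept_records,
        design_states=list(dataset.design_states),
        provenance=provenance,
    )


def response_rate_percent(
    recruited: int = published.STUDY_COUNTS["recruited"],
    usable_addresses: int = published.STUDY_COUNTS["usable_addresses"],
) -> float:
    """Survey response rate in percent (recruited / usable addresses)."""
    if usable_addresses <= 0:
        raise ValueError("usable_addresses must be positive")
    return 100.0 * recruited / usable_addresses


# ---------------------------------------------------------------------------
# canonical exchange formats
# ---------------------------------------------------------------------------

def write_valuations(dataset: SurveyDataset, path) -> None:
    """Write the valuation CSV (respondent_id, state_code, position, value;
    empty value cell = missing).  Floats are written with full precision so
    the round trip is lossless."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["respondent_id", "state_code", "position", "value"])
        for rec in dataset.records:
            writer.writerow(
                [
                    rec.respondent_id,
                    rec.state.code,
                    rec.position,
                    "" if rec.value is None else repr(rec.value),
                ]
            )


def read_valuations(path) -> SurveyDataset:
    """Read a valuation CSV written by :func:`write_valuations` (or prepared
    externally in the same layout)."""
    respondents: dict[str, Respondent] = {}
    records: list[ValuationRecord] = []
    states: dict[str, HealthState] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        needed = {"respondent_id", "state_code", "position", "value"}
        if reader.fieldnames is None or not needed.issubset(reader.fieldnames):
            raise ValueError(f"valuation CSV must have columns {sorted(needed)}")
        for i, row in enumerate(reader, start=2):
            try:
                state = parse_state(row["state_code"])
                position = int(row["position"])
                raw = row["value"].strip()
                value = None if raw == "" else float(raw)
            except (ValueError, KeyError) as exc:
                raise ValueError(f"bad valuation record at line {i}: {exc}") from exc
            if value is not None and not -1.0 <= value <= 1.0:
                raise ValueError(
                    f"value {value} outside [-1, 1] at line {i}"
                )
            rid = row["respondent_id"]
            respondents.setdefault(rid, Respondent(id=rid))
            states.setdefault(state.code, state)
            records.append(ValuationRecord(rid, state, value, position))
    return SurveyDataset(
        respondents=list(respondents.values()),
        records=records,
        design_states=[states[c] for c in sorted(states)],
        provenance={"recruited": len(respondents)},
    )


def write_provenance(dataset: SurveyDataset, path) -> None:
    """Write the stage → count provenance report as JSON."""
    with open(path, "w") as fh:
        json.dump(dataset.provenance, fh, indent=2)
        fh.write("\n")
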