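"""SF-6D health-state descriptive system.

The SF-6D classifies health on six dimensions — physical functioning (PF),
role limitations (RL), social functioning (SF), pain (PAIN), mental health
(MH) and vitality (VIT) — with 6, 4, 5, 6, 5 and 5 levels respectively.
Level 1 of every dimension means no loss of health, so ``111111`` is full
health and ``645655`` (the "pits") is the worst describable state.  The
system spans 6*4*5*6*5*5 = 18,000 distinct states.

Regression models of valuation data represent each state by 25 dummy
indicators, one per level above 1 of each dimension, plus an optional
``most`` indicator that flags states containing any dimension at a
most-severe level (an interaction term capturing an extra decrement for
extreme states).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DIMENSIONS",
    "DIMENSION_LEVELS",
    "DUMMY_NAMES",
    "MOST_SEVERE_LEVELS",
    "N_DUMMIES",
    "N_STATES",
    "PERFECT_HEALTH",
    "PITS",
    "HealthState",
    "DummyVector",
    "parse_state",
    "enumerate_states",
    "dummy_vector",
    "dummy_matrix",
    "read_state_list",
]

#: Dimension short names, in the fixed code order.
DIMENSIONS: tuple[str, ...] = ("PF", "RL", "SF", "PAIN", "MH", "VIT")

#: Number of levels per dimension, aligned with :data:`DIMENSIONS`.
DIMENSION_LEVELS: tuple[int, ...] = (6, 4, 5, 6, 5, 5)

#: Levels counted as "most severe" per dimension (levels 4-6 for PF,
#: 3-4 for RL, 5-6 for PAIN, 4-5 for SF, MH and VIT).
MOST_SEVERE_LEVELS: dict[str, frozenset[int]] = {
    "PF": frozenset({4, 5, 6}),
    "RL": frozenset({3, 4}),
    "SF": frozenset({4, 5}),
    "PAIN": frozenset({5, 6}),
    "MH": frozenset({4, 5}),
    "VIT": frozenset({4, 5}),
}

#: Dummy-column names in the canonical block order (PF2..PF6, RL2..RL4,
#: SF2..SF5, PAIN2..PAIN6, MH2..MH5, VIT2..VIT5).  All coefficient tables
#: and draw files use this order.
DUMMY_NAMES: tuple[str, ...] = tuple(
    f"{dim}{lvl}"
    for dim, nlev in zip(DIMENSIONS, DIMENSION_LEVELS)
    for lvl in range(2, nlev + 1)
)

N_DUMMIES: int = len(DUMMY_NAMES)  # 25
N_STATES: int = int(np.prod(DIMENSION_LEVELS))  # 18,000

PERFECT_HEALTH: str = "111111"
PITS: str = "645655"


class StateFormatError(ValueError):
    """Raised when a state code is not a 6-digit string."""


class StateValidityError(ValueError):
    """Raised when a digit lies outside its dimension's level range."""


@dataclass(frozen=True, order=True)
class HealthState:
    """One SF-6D health state.

    Parameters
    ----------
    levels
        Ordered sextuple of 1-based levels, one per dimension in the order
        PF, RL, SF, PAIN, MH, VIT.
    """

    levels: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != len(DIMENSIONS):
            raise StateFormatError(
                f"expected {len(DIMENSIONS)} levels, got {len(self.levels)}"
            )
        for dim, lvl, nmax in zip(DIMENSIONS, self.levels, DIMENSION_LEVELS):
            if not isinstance(lvl, int):
                raise StateFormatError(f"level for {dim} must be an integer")
            if not 1 <= lvl <= nmax:
                raise StateValidityError(
                    f"level {lvl} out of range for dimension {dim} (1..{nmax})"
                )

    @property
    def code(self) -> str:
        """6-character digit string, e.g. ``'645655'`` for the pits state."""
        return "".join(str(lvl) for lvl in self.levels)

    @classmethod
    def from_code(cls, code: str) -> "HealthState":
        return parse_state(code)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_state(code: str) -> HealthState:
    """Parse a 6-digit state code into a :class:`HealthState`.

    Raises :class:`StateFormatError` for malformed input and
    :class:`StateValidityError` for an out-of-range level (e.g. RL above 4).
    """
    if not isinstance(code, str):
        raise StateFormatError(f"state code must be a string, got {type(code)!r}")
    code = code.strip()
    if len(code) != 6 or not code.isdigit():
        raise StateFormatError(f"state code must be exactly 6 digits, got {code!r}")
    return HealthState(tuple(int(c) for c in code))


def enumerate_states() -> list[HealthState]:
    """All 18,000 valid states, in lexicographic code order.

    The first element is ``111111`` (full health) and the last ``645655``
    (the pits).
    """
    return [
        HealthState(levels)
        for levels in itertools.product(
            *(range(1, nmax + 1) for nmax in DIMENSION_LEVELS)
        )
    ]


@dataclass(frozen=True)
class DummyVector:
    """Dummy representation of one state.

    ``values`` holds the 25 level indicators in :data:`DUMMY_NAMES` order;
    ``most`` is 1 when any dimension sits at a most-severe level.
    """

    values: tuple[int, ...]
    most: int

    def as_array(self, include_most: bool = False) -> np.ndarray:
        arr = np.asarray(self.values, dtype=float)
        if include_most:
            arr = np.append(arr, float(self.most))
        return arr


def _has_most_severe(state: HealthState) -> bool:
    return any(
        lvl in MOST_SEVERE_LEVELS[dim] for dim, lvl in zip(DIMENSIONS, state.levels)
    )


def dummy_vector(state: HealthState) -> DummyVector:
    """Map a state to its 25 level dummies and the ``most`` indicator.

    Level 1 is the baseline of each dimension and carries no dummy, so
    ``111111`` maps to the all-zero vector with ``most = 0``.
    """
    values = []
    for dim, lvl, nmax in zip(DIMENSIONS, state.levels, DIMENSION_LEVELS):
        for cand in range(2, nmax + 1):
            values.append(1 if lvl == cand else 0)
    return DummyVector(tuple(values), 1 if _has_most_severe(state) else 0)


def dummy_matrix(states: list[HealthState], include_most: bool = False) -> np.ndarray:
    """Stack dummy vectors for a list of states into an (n, 25[+1]) array."""
    return np.array(
        [dummy_vector(s).as_array(include_most=include_most) for s in states],
        dtype=float,
    )


def read_state_list(path) -> list[HealthState]:
    """Read a plain-text list of state codes (one per line, blank lines and
    ``#`` comments ignored)."""
    states = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            states.append(parse_state(line))
    return states
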