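"""Refusal probabilities and treatment uptake.

Refusal exists only in the intervention arm: a patient offered the
intervention may refuse it (probability ``p_i``) and the clinician may
refuse to offer it (``q_i``).  Scenarios control the cohort-average refusal
and how strongly refusal tracks the individual's underlying event risk, by
spreading individual probabilities on an equally spaced grid between a lower
and an upper limit and handing them out in the order of the risk frailty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "CORRELATION_LEVELS",
    "RefusalSpec",
    "refusal_limits",
    "assign_refusal_probs",
    "realize_uptake",
]

Level = Literal["zero", "low", "medium", "high"]
Direction = Literal["positive", "negative"]

#: limit half-widths as multiples of the mean p: (UL - LL) / 2 = width * p
CORRELATION_LEVELS: dict[str, float] = {
    "zero": 0.0,
    "low": 1.0 / 3.0,
    "medium": 2.0 / 3.0,
    "high": 1.0,
}


@dataclass(frozen=True)
class RefusalSpec:
    """Average refusal rates and their coupling to event risk.

    ``p`` is the cohort-average patient refusal probability and ``q`` the
    average clinician refusal probability.  ``level`` sets the spread of the
    individual patient probabilities around ``p`` (zero/low/medium/high, i.e.
    limits (p,p), (2p/3,4p/3), (p/3,5p/3), (0,2p)); ``direction`` sets
    whether higher-risk individuals get the higher refusal probabilities
    (positive) or the lower ones (negative).  Clinician probabilities get
    their own, independent structure (``q_level``, ``q_direction``); by
    default they are uncorrelated with risk.
    """

    p: float = 0.0
    q: float = 0.0
    level: Level = "zero"
    direction: Direction = "positive"
    q_level: Level = "zero"
    q_direction: Direction = "positive"

    def __post_init__(self) -> None:
        for name in ("p", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5], got {v}")
        for name in ("level", "q_level"):
            if getattr(self, name) not in CORRELATION_LEVELS:
                raise ValueError(f"unknown correlation level {getattr(self, name)!r}")
        for name in ("direction", "q_direction"):
            if getattr(self, name) not in ("positive", "negative"):
                raise ValueError(f"unknown direction {getattr(self, name)!r}")


def refusal_limits(p: float, level: str) -> tuple[float, float]:
    """Lower and upper limit of individual refusal probabilities.

    The limits are symmetric about the mean: (p, p) at level zero widening
    to (0, 2p) at level high, so the average refusal is ``p`` at every level.
    """
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"p must lie in [0, 0.5], got {p}")
    try:
        width = CORRELATION_LEVELS[level]
    except KeyError:
        raise ValueError(f"unknown correlation level {level!r}") from None
    ll = (1.0 - width) * p
    ul = (1.0 + width) * p
    if ul > 1.0:
        raise ValueError(f"upper limit {ul} exceeds 1 for p={p}, level={level!r}")
    return ll, ul


def assign_refusal_probs(
    frailties: np.ndarray, mean: float, level: str, direction: str
) -> np.ndarray:
    """Individual refusal probabilities, equally spaced and ordered by risk.

    The n probabilities are the grid ``LL + k*(UL-LL)/(n-1)``, k = 0..n-1,
    assigned by the rank of each individual's frailty: under ``positive``
    direction the highest-risk individual receives the largest probability,
    under ``negative`` the smallest.  The arithmetic mean is exactly the
    target ``mean`` at every level, direction and n; ties in the frailty
    (measure-zero for continuous draws) are broken by original index.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    eps = np.asarray(frailties, dtype=float)
    n = eps.shape[0]
    ll, ul = refusal_limits(mean, level)
    if n == 1:
        return np.array([mean])
    grid = np.linspace(ll, ul, n)
    if direction == "negative":
        grid = grid[::-1]
    # rank of each individual's frailty, ascending, stable in the input order
    ranks = np.empty(n, dtype=np.intp)
    ranks[np.argsort(eps, kind="stable")] = np.arange(n)
    return grid[ranks]


def realize_uptake(
    z: np.ndarray,
    p_i: np.ndarray,
    q_i: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Treatment actually received, ``X_i = min{Bern(1-p_i), Bern(1-q_i)}``.

    Everyone allocated to standard of care receives it (X = 0 wherever
    Z = 0); an individual allocated to the intervention receives it only if
    neither the patient nor the clinician refuses, the two refusals being
    independent.
    """
    z = np.asarray(z)
    p_i = np.asarray(p_i, dtype=float)
    q_i = np.asarray(q_i, dtype=float)
    if not (z.shape == p_i.shape == q_i.shape):
        raise ValueError("z, p_i and q_i must have equal lengths")
    accept_patient = rng.random(z.shape) < 1.0 - p_i
    accept_clinician = rng.random(z.shape) < 1.0 - q_i
    return (z.astype(bool) & accept_patient & accept_clinician).astype(np.int8)
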