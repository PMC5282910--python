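"""Simulate one trial-within-cohort with refusal and competing mortality.

One simulated trial walks through the design in order: draw the cohort's
frailties, hand out refusal probabilities by risk rank, randomise 4:1
standard-of-care:intervention, realise treatment uptake, draw latent CVD and
mortality times from the shared-frailty hazards, and censor at whichever of
mortality or the administrative follow-up limit comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .model import ModelParams, draw_frailties, sample_event_time
from .refusal import RefusalSpec, assign_refusal_probs, realize_uptake

__all__ = ["Scenario", "TrialData", "randomize", "simulate_trial"]


@dataclass(frozen=True)
class Scenario:
    """One trial configuration.

    ``allocation`` is the control:intervention ratio as a pair of positive
    integers, default ``(4, 1)``.  ``recruitment`` records which sample-size
    assumption produced ``n_obs``: ``"without_refusal"`` sizes the trial as
    if everyone offered the intervention takes it, ``"with_refusal"``
    inflates for the expected refusal rate.  ``n_obs`` may be left ``None``
    and resolved later by the sizing engine.
    """

    refusal: RefusalSpec = field(default_factory=RefusalSpec)
    recruitment: str = "without_refusal"
    allocation: tuple[int, int] = (4, 1)
    n_obs: Optional[int] = None
    n_sim: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recruitment not in ("without_refusal", "with_refusal"):
            raise ValueError(f"unknown recruitment method {self.recruitment!r}")
        if len(self.allocation) != 2 or any(
            int(a) != a or a < 1 for a in self.allocation
        ):
            raise ValueError("allocation must be a pair of positive integers")
        if self.n_sim < 1:
            raise ValueError("n_sim must be at least 1")
        if self.n_obs is not None and self.n_obs < sum(self.allocation):
            raise ValueError("n_obs smaller than one allocation block")

    def with_n_obs(self, n_obs: int) -> "Scenario":
        return replace(self, n_obs=int(n_obs))


@dataclass
class TrialData:
    """Observed data of one simulated trial (plus optional latent fields).

    Observed per individual: follow-up time ``y`` (years), censoring
    indicator ``c`` (1 = censored, 0 = CVD event observed), allocation ``z``
    and treatment received ``x``.  ``event = 1 - c`` is the conventional
    event flag used by survival fitters.  When ``keep_latent`` was requested
    the generating quantities (frailty, latent times, refusal probabilities)
    ride along for diagnostics.
    """

    y: np.ndarray
    c: np.ndarray
    z: np.ndarray
    x: np.ndarray
    epsilon: Optional[np.ndarray] = None
    t_c: Optional[np.ndarray] = None
    t_m: Optional[np.ndarray] = None
    p_i: Optional[np.ndarray] = None
    q_i: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def event(self) -> np.ndarray:
        """Event indicator (1 = CVD event observed), the complement of c."""
        return 1 - self.c

    def to_frame(self, latent: bool = False) -> pd.DataFrame:
        """Tidy table with columns (id, y, c, event, z, x).

        ``c`` follows the simulation convention 1 = censored; ``event`` is
        the conventional flag 1 = event, provided so downstream survival
        software is never fed the censoring indicator with the wrong sign.
        """
        df = pd.DataFrame(
            {
                "id": np.arange(self.n),
                "y": self.y,
                "c": self.c,
                "event": self.event,
                "z": self.z,
                "x": self.x,
            }
        )
        if latent:
            for name in ("epsilon", "t_c", "t_m", "p_i", "q_i"):
                val = getattr(self, name)
                if val is not None:
                    df[name] = val
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialData":
        """Build from a table with columns (y, z, x) and either c or event."""
        if "c" in df.columns:
            c = np.asarray(df["c"], dtype=np.int8)
        elif "event" in df.columns:
            c = 1 - np.asarray(df["event"], dtype=np.int8)
        else:
            raise ValueError("need a 'c' (1=censored) or 'event' (1=event) column")
        kwargs = {}
        for name in ("epsilon", "t_c", "t_m", "p_i", "q_i"):
            if name in df.columns:
                kwargs[name] = np.asarray(df[name], dtype=float)
        return cls(
            y=np.asarray(df["y"], dtype=float),
            c=c,
            z=np.asarray(df["z"], dtype=np.int8),
            x=np.asarray(df["x"], dtype=np.int8),
            **kwargs,
        )


def randomize(
    n: int, allocation: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Allocate exactly ``round(n * i / (c + i))`` individuals to intervention.

    A uniformly random permutation fixes *which* individuals are selected;
    the arm sizes themselves are deterministic in ``n`` (exact allocation,
    e.g. n=100 at 4:1 gives exactly 20 intervention).
    """
    total = sum(allocation)
    if n < total:
        raise ValueError(f"n={n} smaller than one allocation block of {total}")
    n_int = int(round(n * allocation[1] / total))
    z = np.zeros(n, dtype=np.int8)
    z[rng.permutation(n)[:n_int]] = 1
    return z


def simulate_trial(
    params: ModelParams,
    scenario: Scenario,
    rng: np.random.Generator,
    keep_latent: bool = False,
) -> TrialData:
    """Generate one complete trial dataset.

    Steps, in order: (1) frailties; (2) patient and clinician refusal
    probabilities assigned by frailty rank; (3) randomisation; (4) uptake
    ``X = min{Bern(1-p_i), Bern(1-q_i)}`` in the intervention arm; (5)–(6)
    latent CVD and mortality times from the individual hazards
    ``H_c(t) = (t/lambda_c)^gamma_c * e^(beta*X + eps)`` and
    ``H_m(t) = (t/lambda_m)^gamma_m * e^eps``; (7) censoring: the observed
    time is ``min(t_c, t_m, t_max)`` and an individual is censored whenever
    death or administrative follow-up precedes the CVD event.
    """
    if scenario.n_obs is None:
        raise ValueError("scenario.n_obs must be resolved before simulation")
    n = scenario.n_obs
    spec = scenario.refusal

    eps = draw_frailties(n, params.sigma, rng)
    p_i = assign_refusal_probs(eps, spec.p, spec.level, spec.direction)
    q_i = assign_refusal_probs(eps, spec.q, spec.q_level, spec.q_direction)
    z = randomize(n, scenario.allocation, rng)
    x = realize_uptake(z, p_i, q_i, rng)

    t_c = sample_event_time(
        params.lambda_c, params.gamma_c, params.beta * x + eps, rng
    )
    t_m = sample_event_time(params.lambda_m, params.gamma_m, eps, rng)

    y = np.minimum(np.minimum(t_c, t_m), params.t_max)
    c = (t_c >= np.minimum(t_m, params.t_max)).astype(np.int8)

    if keep_latent:
        return TrialData(y=y, c=c, z=z, x=x, epsilon=eps, t_c=t_c, t_m=t_m,
                         p_i=p_i, q_i=q_i)
    return TrialData(y=y, c=c, z=z, x=x)
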