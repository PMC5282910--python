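"""Replicate loops, performance summaries, and simulation-based sample size.

A scenario is evaluated by simulating many independent trials, refitting the
chosen estimators on each, and aggregating: mean log-hazard-ratio estimate,
relative bias in percent, power (fraction of Wald p-values below alpha) and
the empirical standard error, i.e. the SD of the estimates across
replicates.  The Monte-Carlo SE of the *mean* estimate (SD / sqrt(n_sim)) is
reported separately so the two spreads are never conflated.

Sample sizes come from the same machinery run in reverse: find the smallest
trial size whose simulated ITT power reaches the target.  Recruitment
"without refusal" sizes the trial assuming full uptake; recruitment "with
refusal" assumes the expected refusal rate but treats it as non-informative
(uncorrelated with risk) for the purpose of the calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxph import DegenerateDesignError
from .estimators import METHODS, FitResult, analyze_trial
from .model import ModelParams
from .refusal import RefusalSpec
from .simulate import Scenario, simulate_trial

__all__ = [
    "ScenarioSummary",
    "ReplicateFits",
    "run_replicates",
    "summarize",
    "simulated_power",
    "SampleSizeResult",
    "required_sample_size",
]


@dataclass(frozen=True)
class ScenarioSummary:
    """Per-scenario, per-method aggregate over replicates."""

    method: str
    n_sim: int
    mean_beta: float
    rel_bias_pct: float
    power: float
    empirical_se: float
    mc_se_of_mean: float
    n_failed: int = 0


@dataclass
class ReplicateFits:
    """Fits of one scenario's replicate trials, per method.

    Degenerate fits (no events, weak instrument, ...) are counted in
    ``failures`` rather than silently dropped, so power denominators can be
    audited.
    """

    fits: dict[str, list[FitResult]]
    failures: dict[str, int] = field(default_factory=dict)

    def estimates(self, method: str) -> np.ndarray:
        return np.array([f.beta_hat for f in self.fits[method]])

    def p_values(self, method: str) -> np.ndarray:
        return np.array([f.p_value for f in self.fits[method]])


def run_replicates(
    params: ModelParams,
    scenario: Scenario,
    methods=METHODS,
    n_sim: int | None = None,
    seed: int | None = None,
) -> ReplicateFits:
    """Simulate ``n_sim`` trials and analyse each with all requested methods.

    Every method sees the same replicate datasets.  Each replicate draws its
    own random substream spawned deterministically from the seed, so results
    do not depend on evaluation order.
    """
    n_sim = scenario.n_sim if n_sim is None else n_sim
    seed = scenario.seed if seed is None else seed
    if scenario.n_obs is None:
        raise ValueError("scenario.n_obs must be resolved before replication")
    fits: dict[str, list[FitResult]] = {m: [] for m in methods}
    failures: dict[str, int] = {m: 0 for m in methods}
    for child in np.random.SeedSequence(seed).spawn(n_sim):
        trial = simulate_trial(params, scenario, np.random.default_rng(child))
        for m in methods:
            try:
                fits[m].append(analyze_trial(trial, methods=(m,))[m])
            except DegenerateDesignError:
                failures[m] += 1
    return ReplicateFits(fits=fits, failures=failures)


def summarize(
    fits: list[FitResult], beta_true: float, alpha: float = 0.05, n_failed: int = 0
) -> ScenarioSummary:
    """Aggregate one method's replicate fits into a ScenarioSummary.

    ``rel_bias_pct`` is ``(mean - beta_true) / beta_true * 100``: for a
    protective (negative) true effect, estimates attenuated toward zero give
    negative relative bias and overestimates give positive.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to summarise")
    methods = {f.method for f in fits}
    if len(methods) != 1:
        raise ValueError(f"fits mix methods: {sorted(methods)}")
    beta = np.array([f.beta_hat for f in fits])
    pvals = np.array([f.p_value for f in fits])
    mean = float(beta.mean())
    sd = float(beta.std(ddof=1))
    return ScenarioSummary(
        method=methods.pop(),
        n_sim=len(fits),
        mean_beta=mean,
        rel_bias_pct=(mean - beta_true) / beta_true * 100.0,
        power=float((pvals < alpha).mean()),
        empirical_se=sd,
        mc_se_of_mean=sd / np.sqrt(len(fits)),
        n_failed=n_failed,
    )


def simulated_power(
    n_obs: int,
    params: ModelParams,
    scenario: Scenario,
    method: str = "ITT",
    n_rep: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of ``n_rep`` simulated trials of size ``n_obs`` rejecting at
    ``alpha`` with the chosen method."""
    if n_rep < 50:
        raise ValueError("n_rep below 50 gives an unusable power estimate")
    rep = run_replicates(
        params, scenario.with_n_obs(n_obs), methods=(method,), n_sim=n_rep, seed=seed
    )
    return float((rep.p_values(method) < alpha).mean())


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a sample-size search, with its evaluation trace."""

    n_obs: int
    power: float
    recruitment: str
    method: str
    target_power: float
    trace: tuple[tuple[int, int, float], ...]  # (n, n_rep, power)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace, columns=["n_obs", "n_rep", "power"])


def required_sample_size(
    params: ModelParams,
    recruitment: str = "without_refusal",
    assumed_refusal: tuple[float, float] = (0.0, 0.0),
    target_power: float = 0.80,
    alpha: float = 0.05,
    allocation: tuple[int, int] = (4, 1),
    method: str = "ITT",
    n_rep: int = 200,
    n_rep_final: int = 1000,
    granularity: int = 50,
    n_min: int = 100,
    n_max: int = 1_000_000,
    seed: int = 0,
) -> SampleSizeResult:
    """Smallest trial size (to ``granularity``) reaching the target power.

    The power at a candidate ``n`` is simulated under the recruitment
    assumption: no refusal at all for ``"without_refusal"``, or random
    (risk-uncorrelated) refusal at the ``assumed_refusal`` rates for
    ``"with_refusal"``.  The search doubles ``n`` from ``n_min`` until the
    target is bracketed, bisects down to ``granularity`` using ``n_rep``
    replicates per evaluation (seeded deterministically per candidate so the
    search is stable), then confirms the candidate with ``n_rep_final``
    replicates, stepping up by ``granularity`` if the confirmation falls
    short.
    """
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    if recruitment == "without_refusal":
        spec = RefusalSpec()
    elif recruitment == "with_refusal":
        spec = RefusalSpec(p=assumed_refusal[0], q=assumed_refusal[1], level="zero",
                           q_level="zero")
    else:
        raise ValueError(f"unknown recruitment method {recruitment!r}")
    base = Scenario(refusal=spec, recruitment=recruitment, allocation=allocation)
    trace: list[tuple[int, int, float]] = []

    def power_at(n: int, reps: int) -> float:
        eval_seed = np.random.SeedSequence([seed, n]).generate_state(1)[0] % (2**31)
        pw = simulated_power(
            n, params, base, method=method, n_rep=reps, seed=int(eval_seed),
            alpha=alpha,
        )
        trace.append((n, reps, pw))
        return pw

    # bracket by doubling
    lo, hi = n_min, n_min
    while power_at(hi, n_rep) < target_power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise RuntimeError(
                f"target power {target_power} not reached within n <= {n_max}"
            )
    # bisect down to granularity
    while hi - lo > granularity:
        mid = (lo + hi) // 2
        if power_at(mid, n_rep) >= target_power:
            hi = mid
        else:
            lo = mid
    n_star = int(np.ceil(hi / granularity) * granularity)
    # confirm with the larger replicate count
    pw = power_at(n_star, n_rep_final)
    while pw < target_power and n_star < n_max:
        n_star += granularity
        pw = power_at(n_star, n_rep_final)
    return SampleSizeResult(
        n_obs=n_star,
        power=pw,
        recruitment=recruitment,
        method=method,
        target_power=target_power,
        trace=tuple(trace),
    )
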