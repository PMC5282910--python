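"""Scenario grids: run one cell or a whole factorial of refusal scenarios.

A grid crosses average refusal probabilities with correlation levels,
directions and recruitment methods.  Every cell simulates its own set of
replicate trials (a fresh substream per cell), analyses each replicate with
all four methods on the *same* data, and emits one tidy row per cell and
method.  Trial sizes are resolved once per (recruitment, p, q) combination
by the simulation-based sizing engine and cached, since sizing is the
expensive step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .estimators import METHODS
from .model import ModelParams
from .performance import ScenarioSummary, required_sample_size, run_replicates, summarize
from .refusal import RefusalSpec
from .simulate import Scenario

__all__ = ["GridConfig", "run_scenario", "run_grid", "load_config"]

logger = logging.getLogger(__name__)

_CELL_KEYS = ["p", "q", "level", "direction", "recruitment"]


@dataclass(frozen=True)
class GridConfig:
    """Declarative description of a scenario grid.

    Cells are the cross product of ``p_values`` x ``levels`` x ``directions``
    x ``recruitments`` (clinician refusal ``q`` fixed, default 0).  ``n_obs``
    may pin a common trial size; otherwise each recruitment/p/q combination
    is sized by simulation at ``sizing_n_rep`` replicates per evaluation.
    """

    params: ModelParams = field(default_factory=ModelParams)
    p_values: Sequence[float] = (0.1, 0.2, 0.3)
    q: float = 0.0
    levels: Sequence[str] = ("zero", "low", "medium", "high")
    directions: Sequence[str] = ("positive", "negative")
    recruitments: Sequence[str] = ("without_refusal",)
    n_sim: int = 1000
    seed: int = 0
    n_obs: Optional[int] = None
    methods: Sequence[str] = METHODS
    sizing_n_rep: int = 200
    sizing_n_rep_final: int = 1000
    out: Optional[str] = None

    def cells(self) -> list[Scenario]:
        out = []
        i = 0
        for recruitment in self.recruitments:
            for p in self.p_values:
                for direction in self.directions:
                    for level in self.levels:
                        out.append(
                            Scenario(
                                refusal=RefusalSpec(
                                    p=p, q=self.q, level=level, direction=direction
                                ),
                                recruitment=recruitment,
                                n_obs=self.n_obs,
                                n_sim=self.n_sim,
                                seed=_cell_seed(self.seed, i),
                            )
                        )
                        i += 1
        return out


def _cell_seed(master: int, index: int) -> int:
    import numpy as np

    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


def load_config(path: str | Path) -> GridConfig:
    """Read a GridConfig from YAML or JSON."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    params = ModelParams(**raw.pop("params", {}))
    known = {f.name for f in dataclasses.fields(GridConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return GridConfig(params=params, **raw)


def run_scenario(
    params: ModelParams,
    scenario: Scenario,
    methods: Sequence[str] = METHODS,
    alpha: float = 0.05,
) -> tuple[dict[str, ScenarioSummary], pd.DataFrame]:
    """Evaluate one grid cell: replicate, fit all methods, summarise.

    Returns the per-method summaries and the per-replicate estimates table
    (one row per replicate and method).
    """
    rep = run_replicates(params, scenario, methods=methods)
    summaries = {}
    rows = []
    for m in methods:
        summaries[m] = summarize(
            rep.fits[m], params.beta, alpha=alpha, n_failed=rep.failures[m]
        )
        if rep.failures[m]:
            logger.warning(
                "%d/%d degenerate %s fits in scenario %s",
                rep.failures[m], scenario.n_sim, m, scenario,
            )
        for j, f in enumerate(rep.fits[m]):
            rows.append(
                {"replicate": j, "method": m, "beta_hat": f.beta_hat,
                 "se_hat": f.se_hat, "p_value": f.p_value, "n_used": f.n_used}
            )
    return summaries, pd.DataFrame(rows)


def _cell_row(scenario: Scenario, method: str, s: ScenarioSummary) -> dict:
    return {
        "p": scenario.refusal.p,
        "q": scenario.refusal.q,
        "level": scenario.refusal.level,
        "direction": scenario.refusal.direction,
        "recruitment": scenario.recruitment,
        "n_obs": scenario.n_obs,
        "method": method,
        "n_sim": s.n_sim,
        "mean_beta": s.mean_beta,
        "rel_bias_pct": s.rel_bias_pct,
        "power": s.power,
        "empirical_se": s.empirical_se,
        "mc_se_of_mean": s.mc_se_of_mean,
        "n_failed": s.n_failed,
    }


def run_grid(config: GridConfig) -> pd.DataFrame:
    """Run every cell of the grid, resuming from ``config.out`` if present.

    Emits a long-format table keyed by (p, q, level, direction, recruitment,
    method).  Cells whose key already appears in the output file are skipped,
    so an interrupted run can be restarted; partial results are flushed to
    disk after every cell.
    """
    cells = config.cells()
    out_path = Path(config.out) if config.out else None
    done: pd.DataFrame | None = None
    if out_path is not None and out_path.exists():
        done = pd.read_csv(out_path)
        logger.info("resuming: %d rows already in %s", len(done), out_path)

    size_cache: dict[tuple, int] = {}

    def resolve_n_obs(sc: Scenario) -> int:
        if sc.n_obs is not None:
            return sc.n_obs
        key = (sc.recruitment, sc.refusal.p, sc.refusal.q)
        if key not in size_cache:
            res = required_sample_size(
                config.params,
                recruitment=sc.recruitment,
                assumed_refusal=(sc.refusal.p, sc.refusal.q),
                n_rep=config.sizing_n_rep,
                n_rep_final=config.sizing_n_rep_final,
                seed=config.seed,
            )
            logger.info("sized %s -> n_obs=%d (power %.3f)", key, res.n_obs, res.power)
            size_cache[key] = res.n_obs
        return size_cache[key]

    rows: list[dict] = [] if done is None else done.to_dict("records")
    for sc in cells:
        key_vals = (sc.refusal.p, sc.refusal.q, sc.refusal.level,
                    sc.refusal.direction, sc.recruitment)
        if done is not None and not done.empty:
            mask = (done[_CELL_KEYS] == pd.Series(dict(zip(_CELL_KEYS, key_vals)))).all(
                axis=1
            )
            if mask.any():
                logger.info("skipping completed cell %s", key_vals)
                continue
        sc = sc.with_n_obs(resolve_n_obs(sc))
        logger.info("running cell %s, n_obs=%d, seed=%d", key_vals, sc.n_obs, sc.seed)
        summaries, _ = run_scenario(config.params, sc, methods=config.methods)
        for m in config.methods:
            rows.append(_cell_row(sc, m, summaries[m]))
        if out_path is not None:
            pd.DataFrame(rows).to_csv(out_path, index=False)
    result = pd.DataFrame(rows)
    return result.sort_values(_CELL_KEYS + ["method"], kind="stable").reset_index(
        drop=True
    )
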