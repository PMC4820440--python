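"""Seeded trial generation from (modulated) decision units.

A simulated dataset mixes up to three response subpopulations:

* ``main`` — latencies from the modulated decision unit (``delta_eff / rate``
  with a fresh Gaussian rate each trial);
* ``early`` — latencies from the zero-mean-promptness early unit (second
  reciprobit line, slope ``sigma_prime``);
* ``express`` — bypass responses emitted only while the express gate is
  open, drawn from a truncated normal over a fixed latency band (floor
  80 ms in humans, 60 ms in monkeys).

Trials whose rate never reaches threshold (rate <= 0) or whose latency
exceeds the response window are recorded as ``censored`` rather than
dropped, so fitters know how many trials were attempted.

Random-draw discipline: for a given seed the generator draws, in fixed
order, the express/early assignment uniforms and then full-length vectors
for every candidate latency, selecting by mask afterwards.  Identical
(config, state, seed) therefore yields a byte-identical dataset.

The two-condition experiment harness simulates a pre block at the resting
modulator state, runs a stimulation schedule (TIMER drive, RIDER drive, or
movement feedback) through the deterministic state updates, and simulates a
post block at the resulting state, returning the full state trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import truncnorm

from .errors import ConfigError
from .later_core import EarlyComponent, LaterUnit
from .modulation import (
    CouplingConfig,
    ModulatorState,
    effective_unit,
    express_gate,
    step_state,
)

__all__ = [
    "TrialSet",
    "ScheduleBlock",
    "SimulationConfig",
    "Intervention",
    "simulate_trials",
    "simulate_emdr_experiment",
]

TRIAL_COLUMNS = ["trial_index", "condition", "subpopulation", "latency_ms"]

SUBPOPULATIONS = ("main", "early", "express", "censored")


@dataclass
class TrialSet:
    """A table of trials: ``trial_index, condition, subpopulation,
    latency_ms`` (latency is NaN for censored rows)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigError(f"TrialSet missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_censored(self) -> int:
        return int((self.data["subpopulation"] == "censored").sum())

    @property
    def latencies_ms(self) -> np.ndarray:
        """Non-censored latencies in milliseconds."""
        return self.data.loc[
            self.data["subpopulation"] != "censored", "latency_ms"
        ].to_numpy(dtype=float)

    @property
    def promptness(self) -> np.ndarray:
        """Promptness (1/s) of the non-censored trials."""
        return 1000.0 / self.latencies_ms

    def subset(self, subpopulation: str) -> "TrialSet":
        return TrialSet(
            self.data[self.data["subpopulation"] == subpopulation].reset_index(
                drop=True
            )
        )


class ScheduleBlock(BaseModel):
    """One block of the stimulation schedule applied between conditions."""

    model_config = ConfigDict(frozen=True)

    n_steps: int = 20
    timer_drive: float = 1.0
    rider_drive: float = 1.0
    movements_per_step: int = 2

    @model_validator(mode="after")
    def _check(self) -> "ScheduleBlock":
        if self.n_steps < 0:
            raise ConfigError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.timer_drive < 0 or self.rider_drive < 0:
            raise ConfigError("schedule drives must be non-negative")
        if self.movements_per_step < 0:
            raise ConfigError("movements_per_step must be >= 0")
        return self


class SimulationConfig(BaseModel):
    """Everything needed to generate a trial dataset.

    Defaults give a human parameterization: a unit with unit threshold
    interval, mean rate 5 /s (median latency 200 ms) and rate SD 1 /s; a
    small early component; an express band of 80–134 ms entered with
    probability ``p_express`` only while the bypass gate is open; and a
    1000 ms response window.
    """

    model_config = ConfigDict(frozen=True)

    unit: LaterUnit = Field(default_factory=LaterUnit)
    early: EarlyComponent = Field(default_factory=EarlyComponent)
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)
    p_express: float = 0.8
    express_floor_ms: float = 80.0
    express_ceiling_ms: float = 134.0
    express_mean_ms: float = 100.0
    express_sd_ms: float = 10.0
    response_window_ms: float = 1000.0
    n_trials: int = 500
    schedule: tuple[ScheduleBlock, ...] = Field(
        default_factory=lambda: (ScheduleBlock(),)
    )

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        problems = []
        if not 0.0 <= self.p_express <= 1.0:
            problems.append(f"p_express must lie in [0, 1], got {self.p_express}")
        if self.early.weight + self.p_express > 1.0 + 1e-12:
            problems.append(
                "mixture weights exceed 1: early.weight + p_express = "
                f"{self.early.weight + self.p_express}"
            )
        if not self.express_floor_ms > 0:
            problems.append("express_floor_ms must be positive")
        if not self.express_ceiling_ms > self.express_floor_ms:
            problems.append(
                f"express_ceiling_ms={self.express_ceiling_ms} must exceed "
                f"express_floor_ms={self.express_floor_ms}"
            )
        if not self.express_sd_ms > 0:
            problems.append("express_sd_ms must be positive")
        if not self.response_window_ms > 0:
            problems.append("response_window_ms must be positive")
        if self.n_trials < 1:
            problems.append(f"n_trials must be >= 1, got {self.n_trials}")
        if problems:
            raise ConfigError("; ".join(problems))
        return self


def simulate_trials(
    cfg: SimulationConfig,
    state: ModulatorState | None = None,
    seed: int = 0,
    condition: str = "baseline",
) -> TrialSet:
    """Generate one seeded trial dataset at a given modulator state.

    Per trial: while the express gate is open an express latency is emitted
    with probability ``p_express``; otherwise the trial is early with
    probability ``early.weight`` (promptness drawn from N(0, sigma_prime^2))
    and main otherwise (rate drawn from the modulated unit).  Non-positive
    rates/promptness and latencies beyond the response window are censored.
    """
    if state is None:
        state = cfg.coupling.baseline_state()
    rng = np.random.default_rng(seed)
    n = cfg.n_trials
    eff = effective_unit(cfg.unit, state, cfg.coupling)
    gate_open = express_gate(state, cfg.coupling)

    u_express = rng.random(n)
    u_early = rng.random(n)
    # Full-length candidate draws keep the stream layout seed-stable.
    a = (cfg.express_floor_ms - cfg.express_mean_ms) / cfg.express_sd_ms
    b = (cfg.express_ceiling_ms - cfg.express_mean_ms) / cfg.express_sd_ms
    express_lat_ms = truncnorm.rvs(
        a, b, loc=cfg.express_mean_ms, scale=cfg.express_sd_ms, size=n, random_state=rng
    )
    early_promptness = rng.normal(0.0, cfg.early.sigma_prime, size=n)
    main_rate = rng.normal(eff.rate_mean, eff.rate_sd, size=n)

    is_express = gate_open & (u_express < cfg.p_express)
    is_early = ~is_express & (u_early < cfg.early.weight)
    is_main = ~is_express & ~is_early

    latency_ms = np.full(n, np.inf)
    latency_ms[is_express] = express_lat_ms[is_express]
    with np.errstate(divide="ignore", invalid="ignore"):
        early_lat = np.where(early_promptness > 0, 1000.0 / early_promptness, np.inf)
        main_lat = np.where(main_rate > 0, 1000.0 * eff.delta / main_rate, np.inf)
    latency_ms[is_early] = early_lat[is_early]
    latency_ms[is_main] = main_lat[is_main]

    censored = latency_ms > cfg.response_window_ms
    subpop = np.where(
        censored,
        "censored",
        np.where(is_express, "express", np.where(is_early, "early", "main")),
    )
    frame = pd.DataFrame(
        {
            "trial_index": np.arange(n, dtype=int),
            "condition": condition,
            "subpopulation": subpop,
            "latency_ms": np.where(censored, np.nan, latency_ms),
        }
    )
    return TrialSet(frame)


Intervention = Literal["timer_boost", "rider_boost", "pursuit_feedback", "none"]

INTERVENTIONS: tuple[str, ...] = ("timer_boost", "rider_boost", "pursuit_feedback", "none")


def _block_inputs(block: ScheduleBlock, intervention: str) -> tuple[float, float, int]:
    if intervention == "timer_boost":
        return block.timer_drive, 0.0, 0
    if intervention == "rider_boost":
        return 0.0, block.rider_drive, 0
    if intervention == "pursuit_feedback":
        return 0.0, 0.0, block.movements_per_step
    return 0.0, 0.0, 0  # none


def simulate_emdr_experiment(
    cfg: SimulationConfig,
    intervention: Intervention = "timer_boost",
    seed: int = 0,
) -> tuple[TrialSet, TrialSet, list[ModulatorState]]:
    """Two-condition experiment: pre trials at rest, stimulation, post trials.

    ``timer_boost`` drives T only (threshold-interval route),
    ``rider_boost`` drives R only (gain route), ``pursuit_feedback`` injects
    executed movements whose feedback increments both T and R, and ``none``
    leaves the state untouched.  Pre and post use seeds ``seed`` and
    ``seed + 1``; the returned trace holds every intermediate state.
    """
    if intervention not in INTERVENTIONS:
        raise ConfigError(
            f"unknown intervention {intervention!r}; expected one of {INTERVENTIONS}"
        )
    state = cfg.coupling.baseline_state()
    trace = [state]
    pre = simulate_trials(cfg, state, seed=seed, condition="pre")
    for block in cfg.schedule:
        timer_drive, rider_drive, movements = _block_inputs(block, intervention)
        for _ in range(block.n_steps):
            state = step_state(state, timer_drive, rider_drive, movements, cfg.coupling)
            trace.append(state)
    post = simulate_trials(cfg, state, seed=seed + 1, condition="post")
    return pre, post, trace
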