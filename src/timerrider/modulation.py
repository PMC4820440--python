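"""TIMER/RIDER attention-inhibition network.

Two modulators regulate every decision unit through a single global
inhibition process I:

* TIMER (threshold-interval modulation) — its signal T shrinks the
  threshold interval of decision units, swivelling the reciprobit line;
* RIDER (rate-of-rise modulation) — its signal R boosts the gain
  (mean rate of rise), shifting the reciprobit line.

T and R live in ``[T0, T1]`` and ``[R0, R1]``; inhibition mirrors their
combined activity linearly, falling from ``I1`` (movement fully suppressed)
to ``I0`` (fully released).  The modulators' effects on unit parameters are
added independently — TIMER touches only the threshold interval, RIDER only
the gain.  When inhibition falls to a configurable level ``theta_express``
an all-or-nothing bypass switch opens and express responses (which skip the
attention-decision path entirely) become possible.

Executed movements feed back: each one increments T and R by
``feedback_gain``, which in turn lowers inhibition — the loop by which
movement stimulation on its own can release the network.

Modulator dynamics are deterministic discrete-time (Euler) updates; the
stochastic element of the model lives entirely in the decision units.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigError, DomainError
from .later_core import LaterUnit

__all__ = [
    "CouplingConfig",
    "ModulatorState",
    "inhibition_level",
    "step_state",
    "effective_unit",
    "express_gate",
]


class CouplingConfig(BaseModel):
    """Bounds, couplings and dynamics of the modulator network.

    Parameters
    ----------
    t0, t1, r0, r1, i0, i1
        Bounds of the TIMER, RIDER and inhibition signals (dimensionless).
    w_t, w_r
        Non-negative inhibition coupling weights, summing to 1: the share of
        the inhibition drop attributed to each modulator.
    c_t
        Maximal fractional reduction of the threshold interval at full TIMER
        engagement, in ``[0, 1)`` so the interval stays positive.
    c_r
        Maximal fractional increase of the mean rate of rise at full RIDER
        engagement, ``>= 0``.
    theta_express
        Inhibition level at or below which the express bypass switch opens
        (inclusive boundary).
    feedback_gain
        Increment to T and to R per executed movement.
    dt
        Time step of the deterministic state updates, seconds.
    """

    model_config = ConfigDict(frozen=True)

    t0: float = 0.0
    t1: float = 1.0
    r0: float = 0.0
    r1: float = 1.0
    i0: float = 0.0
    i1: float = 1.0
    w_t: float = 0.5
    w_r: float = 0.5
    c_t: float = 0.3
    c_r: float = 0.3
    theta_express: float = 0.05
    feedback_gain: float = 0.05
    dt: float = 0.1

    @model_validator(mode="after")
    def _check(self) -> "CouplingConfig":
        problems = []
        if not self.t1 > self.t0:
            problems.append(f"t1={self.t1} must exceed t0={self.t0}")
        if not self.r1 > self.r0:
            problems.append(f"r1={self.r1} must exceed r0={self.r0}")
        if not self.i1 > self.i0:
            problems.append(f"i1={self.i1} must exceed i0={self.i0}")
        if self.w_t < 0 or self.w_r < 0:
            problems.append("coupling weights w_t, w_r must be non-negative")
        if abs(self.w_t + self.w_r - 1.0) > 1e-9:
            problems.append(f"w_t + w_r must equal 1, got {self.w_t + self.w_r}")
        if not 0.0 <= self.c_t < 1.0:
            problems.append(f"c_t must lie in [0, 1), got {self.c_t}")
        if self.c_r < 0:
            problems.append(f"c_r must be >= 0, got {self.c_r}")
        if self.feedback_gain < 0:
            problems.append(f"feedback_gain must be >= 0, got {self.feedback_gain}")
        if not self.dt > 0:
            problems.append(f"dt must be positive, got {self.dt}")
        if problems:
            raise ConfigError("; ".join(problems))
        return self

    def baseline_state(self) -> "ModulatorState":
        """Resting state: modulators at their floors, inhibition maximal."""
        return ModulatorState(t_level=self.t0, r_level=self.r0, i_level=self.i1)


class ModulatorState(BaseModel):
    """Instantaneous TIMER (T), RIDER (R) and inhibition (I) levels."""

    model_config = ConfigDict(frozen=True)

    t_level: float
    r_level: float
    i_level: float


def _check_levels(t_level: float, r_level: float, cfg: CouplingConfig) -> None:
    if not cfg.t0 <= t_level <= cfg.t1:
        raise DomainError(
            f"TIMER level {t_level} outside bounds [{cfg.t0}, {cfg.t1}]"
        )
    if not cfg.r0 <= r_level <= cfg.r1:
        raise DomainError(
            f"RIDER level {r_level} outside bounds [{cfg.r0}, {cfg.r1}]"
        )


def inhibition_level(t_level: float, r_level: float, cfg: CouplingConfig) -> float:
    """Inhibition mirroring the modulators' combined normalized activity.

    ``I = I1 - (I1 - I0) * (w_t * normT + w_r * normR)`` clamped to
    ``[I0, I1]``: exactly linear and strictly decreasing in each modulator
    between the clamps.
    """
    _check_levels(t_level, r_level, cfg)
    norm_t = (t_level - cfg.t0) / (cfg.t1 - cfg.t0)
    norm_r = (r_level - cfg.r0) / (cfg.r1 - cfg.r0)
    i = cfg.i1 - (cfg.i1 - cfg.i0) * (cfg.w_t * norm_t + cfg.w_r * norm_r)
    return min(max(i, cfg.i0), cfg.i1)


def step_state(
    state: ModulatorState,
    timer_drive: float,
    rider_drive: float,
    movements_executed: int,
    cfg: CouplingConfig,
) -> ModulatorState:
    """One deterministic Euler step of the modulator dynamics.

    Each modulator integrates its external drive (``drive * dt``) plus the
    movement feedback (``feedback_gain`` per executed movement), clamped to
    its bounds; inhibition is then recomputed from the new levels.
    """
    if timer_drive < 0 or rider_drive < 0:
        raise DomainError("drives must be non-negative")
    if movements_executed < 0:
        raise DomainError("movement count must be non-negative")
    t_new = state.t_level + timer_drive * cfg.dt + cfg.feedback_gain * movements_executed
    r_new = state.r_level + rider_drive * cfg.dt + cfg.feedback_gain * movements_executed
    t_new = min(max(t_new, cfg.t0), cfg.t1)
    r_new = min(max(r_new, cfg.r0), cfg.r1)
    return ModulatorState(
        t_level=t_new,
        r_level=r_new,
        i_level=inhibition_level(t_new, r_new, cfg),
    )


def effective_unit(
    base: LaterUnit, state: ModulatorState, cfg: CouplingConfig
) -> LaterUnit:
    """Apply the modulators to a decision unit.

    TIMER shrinks the threshold interval by up to the fraction ``c_t``
    (moving ``s_t`` toward ``s0``); RIDER scales the mean rate of rise up by
    up to the fraction ``c_r``.  The two effects are independent and
    additive in the sense that each touches its own parameter only; the
    rate SD is never modulated.  Consequently TIMER-only engagement
    preserves the infinite-time intercept and RIDER-only engagement
    preserves the promptness SD.
    """
    _check_levels(state.t_level, state.r_level, cfg)
    norm_t = (state.t_level - cfg.t0) / (cfg.t1 - cfg.t0)
    norm_r = (state.r_level - cfg.r0) / (cfg.r1 - cfg.r0)
    delta_eff = base.delta * (1.0 - cfg.c_t * norm_t)
    return base.model_copy(
        update={
            "s_t": base.s0 + delta_eff,
            "rate_mean": base.rate_mean * (1.0 + cfg.c_r * norm_r),
        }
    )


def express_gate(state: ModulatorState, cfg: CouplingConfig) -> bool:
    """All-or-nothing bypass switch: open iff ``I <= theta_express``.

    The boundary is inclusive — at exactly the threshold the gate is open.
    """
    return state.i_level <= cfg.theta_express
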