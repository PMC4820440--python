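"""Rise-to-threshold (LATER) decision-unit mathematics.

A LATER unit models reaction time as the first-passage time of a linear
decision signal: on each trial the signal starts at level ``s0``, rises at a
rate drawn once from a Gaussian ``N(rate_mean, rate_sd**2)``, and triggers a
response on reaching the threshold ``s_t``.  With threshold interval
``delta = s_t - s0`` the latency is ``delta / rate``, so *promptness*
(reciprocal latency) is Gaussian with mean ``m = rate_mean / delta`` and SD
``s = rate_sd / delta`` — the *recinormal* latency distribution.

On a reciprobit plot (cumulative probability on a probit scale against
latency on a reciprocal scale) a recinormal sample lies on a straight line.
Two algebraic identities drive everything downstream:

* changing ``delta`` rescales ``m`` and ``s`` together, so the line *swivels*
  about its infinite-time intercept ``-m/s``, which is independent of
  ``delta``;
* changing ``rate_mean`` (the gain) moves ``m`` only, so the line *shifts*
  laterally with its slope (``s``) unchanged.

Rates drawn at or below zero never reach threshold: the latency distribution
is defective with response probability ``Phi(m/s) < 1``.  The CDF below is
the unconditional one (``P(latency <= t)``), so its supremum is the response
probability; quantiles inside the defective mass raise
:class:`~timerrider.errors.UndefinedQuantileError`.

All latencies here are in seconds; the CSV file boundary uses milliseconds.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.stats import norm

from .errors import DomainError, InvalidUnitError, UndefinedQuantileError

__all__ = [
    "LaterUnit",
    "RecinormalParams",
    "EarlyComponent",
    "promptness_params",
    "median_latency",
    "infinite_time_intercept",
    "recinormal_cdf",
    "recinormal_pdf",
    "recinormal_quantile",
    "perturb_unit",
]


class LaterUnit(BaseModel):
    """A single rise-to-threshold decision unit.

    Parameters
    ----------
    s0, s_t
        Start level and final threshold (arbitrary activation units);
        ``s_t > s0`` is required so the threshold interval is positive.
    rate_mean, rate_sd
        Mean and SD of the per-trial rate of rise, in activation units per
        second; ``rate_sd > 0``.
    """

    model_config = ConfigDict(frozen=True)

    s0: float = 0.0
    s_t: float = 1.0
    rate_mean: float = 5.0
    rate_sd: float = 1.0

    @model_validator(mode="after")
    def _check_invariants(self) -> "LaterUnit":
        if not self.s_t > self.s0:
            raise InvalidUnitError(
                f"threshold interval must be positive: s_t={self.s_t} <= s0={self.s0}"
            )
        if not self.rate_sd > 0:
            raise InvalidUnitError(f"rate_sd must be positive, got {self.rate_sd}")
        return self

    @property
    def delta(self) -> float:
        """Threshold interval ``s_t - s0`` (activation units)."""
        return self.s_t - self.s0


class RecinormalParams(BaseModel):
    """Promptness-Gaussian parameterization of a latency distribution.

    ``m`` and ``s`` are the mean and SD of promptness (reciprocal latency,
    units 1/s).  The median latency is ``1/m`` (for ``m > 0``) and the
    reciprobit line meets the infinite-time axis at ``-m/s`` probit units.
    """

    model_config = ConfigDict(frozen=True)

    m: float
    s: float

    @model_validator(mode="after")
    def _check(self) -> "RecinormalParams":
        if not self.s > 0:
            raise DomainError(f"promptness SD must be positive, got {self.s}")
        return self

    @property
    def median_latency(self) -> float:
        """Median latency in seconds (requires ``m > 0``)."""
        if self.m <= 0:
            raise DomainError("median latency undefined for non-positive mean promptness")
        return 1.0 / self.m

    @property
    def infinite_time_intercept(self) -> float:
        """Reciprobit-line value at infinite time, ``-m/s`` (probit units)."""
        return -self.m / self.s

    @property
    def response_probability(self) -> float:
        """Total mass of finite latencies, ``Phi(m/s)``."""
        return float(norm.cdf(self.m / self.s))

    @property
    def miss_probability(self) -> float:
        """Mass of trials that never respond (rate <= 0), ``Phi(-m/s)``."""
        return float(norm.cdf(-self.m / self.s))


class EarlyComponent(BaseModel):
    """The early-response subpopulation: a second reciprobit line through the
    infinite-time axis at zero, characterised by its slope alone.

    The early unit has zero mean promptness, so its only parameter is the
    promptness SD ``sigma_prime`` (1/s); ``weight`` is its mixture
    proportion.  The zero-mean convention pins the early line's
    infinite-time intercept at 0 probit units.
    """

    model_config = ConfigDict(frozen=True)

    sigma_prime: float = 2.0
    weight: float = 0.05

    @model_validator(mode="after")
    def _check(self) -> "EarlyComponent":
        if not self.sigma_prime > 0:
            raise DomainError(f"sigma_prime must be positive, got {self.sigma_prime}")
        if not 0.0 <= self.weight <= 1.0:
            raise DomainError(f"weight must lie in [0, 1], got {self.weight}")
        return self


def promptness_params(unit: LaterUnit) -> RecinormalParams:
    """Map a decision unit to its promptness Gaussian.

    latency = delta / rate with Gaussian rate implies promptness
    1/latency = rate/delta is Gaussian with ``m = rate_mean/delta`` and
    ``s = rate_sd/delta``.
    """
    return RecinormalParams(m=unit.rate_mean / unit.delta, s=unit.rate_sd / unit.delta)


def median_latency(unit: LaterUnit) -> float:
    """Median latency in seconds: the time to traverse the threshold
    interval at the mean rate, ``delta / rate_mean``."""
    if unit.rate_mean <= 0:
        raise DomainError(
            f"median latency undefined for rate_mean={unit.rate_mean} <= 0"
        )
    return unit.delta / unit.rate_mean


def infinite_time_intercept(unit: LaterUnit) -> float:
    """Reciprobit intercept at infinite time, ``-rate_mean/rate_sd``.

    The threshold interval cancels, which is why a pure threshold change
    swivels the line about this point.
    """
    return -unit.rate_mean / unit.rate_sd


def recinormal_cdf(t, p: RecinormalParams):
    """Unconditional recinormal CDF ``P(latency <= t)`` for ``t > 0`` seconds.

    Equals ``1 - Phi((1/t - m)/s)``; approaches the response probability
    ``Phi(m/s)`` as ``t -> inf``.  Accepts scalars or arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise DomainError("recinormal_cdf requires t > 0")
    out = norm.cdf((p.m - 1.0 / t_arr) / p.s)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def recinormal_pdf(t, p: RecinormalParams):
    """Recinormal density ``phi((1/t - m)/s) / (s t^2)`` for ``t > 0`` seconds."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise DomainError("recinormal_pdf requires t > 0")
    out = norm.pdf((1.0 / t_arr - p.m) / p.s) / (p.s * t_arr**2)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def recinormal_quantile(q: float, p: RecinormalParams) -> float:
    """Latency quantile (seconds) inverting :func:`recinormal_cdf`.

    Defined only while the corresponding promptness quantile is positive,
    i.e. for ``q`` below the response probability; beyond that the latency
    is infinite (the trial never responds) and
    :class:`~timerrider.errors.UndefinedQuantileError` is raised.
    """
    if not 0.0 < q < 1.0:
        raise DomainError(f"quantile level must lie in (0, 1), got {q}")
    promptness_q = p.m + p.s * norm.ppf(1.0 - q)
    if promptness_q <= 0:
        raise UndefinedQuantileError(
            f"q={q} exceeds the response probability {p.response_probability:.6g}; "
            "the latency quantile is not finite"
        )
    return 1.0 / promptness_q


PerturbKind = Literal["threshold_change", "gain_change"]


def perturb_unit(unit: LaterUnit, kind: PerturbKind, factor: float) -> LaterUnit:
    """Return a new unit with the threshold interval or the gain rescaled.

    ``threshold_change`` scales ``delta`` by ``factor`` (moving ``s_t``,
    fixing ``s0``) and leaves the infinite-time intercept unchanged — the
    swivel signature.  ``gain_change`` scales ``rate_mean`` by ``factor``
    with ``rate_sd`` untouched, leaving the promptness SD unchanged — the
    shift signature.
    """
    if not factor > 0:
        raise DomainError(f"perturbation factor must be positive, got {factor}")
    if kind == "threshold_change":
        return unit.model_copy(update={"s_t": unit.s0 + unit.delta * factor})
    if kind == "gain_change":
        return unit.model_copy(update={"rate_mean": unit.rate_mean * factor})
    raise DomainError(f"unknown perturbation kind: {kind!r}")
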