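"""Fitting and inference for recinormal reaction-time distributions.

The central objects are promptness (reciprocal latency, 1/s), whose
distribution is Gaussian under the rise-to-threshold model, and the
reciprobit line it traces when cumulative probability (probit scale) is
plotted against latency (reciprocal scale).

Fits
----
* :func:`fit_recinormal` — maximum likelihood for the promptness Gaussian
  ``(m, s)``; with no censoring this is exactly the sample mean and
  population SD of promptness, with censoring an optional right-censored
  likelihood is maximized numerically.
* :func:`fit_early_mixture` — adds the early subpopulation: a zero-mean
  promptness Gaussian of SD ``sigma_prime`` and weight ``pi``, fitted by EM
  from a deterministic initialization.

Two-condition comparison
------------------------
:func:`compare_conditions` fits four nested hypotheses on promptness:

* ``same``   — one Gaussian for both conditions;
* ``swivel`` — common infinite-time intercept (common ratio ``k = m/s``),
  free slopes: the signature of a threshold-interval change;
* ``shift``  — common slope ``s``, free means: the signature of a
  rate-of-rise (gain) change;
* ``full``   — both parameters free per condition,

and classifies the change by likelihood-ratio tests: ``same`` is tested
against ``full`` first; if rejected, ``swivel`` and ``shift`` are each
tested against ``full`` and the verdict is the surviving constrained model
with the higher log-likelihood (both rejected gives ``full``).  All reported
log-likelihoods are on the latency scale (they include the ``t**-2``
Jacobian of the reciprocal transform, a constant shared by every
hypothesis).

Latency classes
---------------
Histogram clusters for human saccade reaction times: anticipatory
(< 80 ms), express (80–134 ms), fast regular (135–179 ms), slow regular
(180–399 ms), late (400 ms and beyond), realized as half-open intervals
[80, 135), [135, 180), [180, 400), [400, inf) so non-integer latencies in
the printed 1 ms gaps are still classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import optimize
from scipy.stats import chi2, norm

from .errors import DomainError, FitError, InsufficientDataError
from .later_core import EarlyComponent, RecinormalParams
from .simulator import TrialSet

__all__ = [
    "FitResult",
    "ConditionComparison",
    "LatencyClassBins",
    "DEFAULT_BINS",
    "fit_recinormal",
    "fit_early_mixture",
    "reciprobit_coordinates",
    "compare_conditions",
    "classify_latency",
    "bin_proportions",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a recinormal (optionally mixture) fit."""

    params: RecinormalParams
    log_likelihood: float
    n_used: int
    n_censored: int
    converged: bool
    early: EarlyComponent | None = None
    boundary: bool = False


@dataclass(frozen=True)
class HypothesisFit:
    """Constrained two-condition fit: per-condition parameters and its
    latency-scale log-likelihood."""

    a: RecinormalParams
    b: RecinormalParams
    log_likelihood: float
    n_free: int


@dataclass(frozen=True)
class ConditionComparison:
    """Nested-model comparison of two conditions with its verdict."""

    fits: dict[str, HypothesisFit]
    statistics: dict[str, float]
    p_values: dict[str, float]
    verdict: Literal["none", "swivel", "shift", "full"]
    alpha: float
    correction: str | None = None


@dataclass(frozen=True)
class LatencyClassBins:
    """Half-open latency classes (ms) partitioning (0, inf)."""

    boundaries_ms: tuple[float, ...] = (80.0, 135.0, 180.0, 400.0)
    labels: tuple[str, ...] = (
        "anticipatory",
        "express",
        "fast_regular",
        "slow_regular",
        "late",
    )

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries_ms) + 1:
            raise DomainError("need exactly one more label than boundary")
        if not all(np.diff(self.boundaries_ms) > 0):
            raise DomainError("class boundaries must be strictly increasing")


DEFAULT_BINS = LatencyClassBins()


def _promptness(trials: TrialSet, minimum: int) -> np.ndarray:
    p = trials.promptness
    if len(p) < minimum:
        raise InsufficientDataError(
            f"need at least {minimum} non-censored trials, got {len(p)}"
        )
    return p


def _jacobian_term(p: np.ndarray) -> float:
    # d(promptness)/d(latency) = promptness**2, with promptness in 1/s.
    return float(2.0 * np.sum(np.log(p / 1000.0)) + len(p) * np.log(1000.0))


def _gauss_loglik(p: np.ndarray, m: float, s: float) -> float:
    z = (p - m) / s
    return float(-0.5 * np.sum(z * z) - len(p) * (np.log(s) + 0.5 * _LOG_2PI))


def _gauss_max_loglik(p: np.ndarray) -> tuple[float, float, float]:
    """Closed-form Gaussian MLE and its log-likelihood."""
    m = float(np.mean(p))
    s = float(np.std(p))  # population (ddof=0) SD: the ML estimate
    if s <= 0:
        raise FitError("degenerate sample: zero promptness variance")
    return m, s, _gauss_loglik(p, m, s)


def fit_recinormal(
    trials: TrialSet,
    censoring: Literal["exclude", "likelihood"] = "exclude",
    window_ms: float = 1000.0,
) -> FitResult:
    """Maximum-likelihood recinormal fit.

    With ``censoring="exclude"`` (default) the fit uses non-censored trials
    only and is the closed-form promptness moment estimate.  With
    ``censoring="likelihood"`` each censored trial contributes the
    probability of no response within ``window_ms`` (which absorbs both
    slow trials and never-responding, non-positive-rate trials) and the
    likelihood is maximized numerically from the moment start.
    """
    p = _promptness(trials, 3)
    n_cens = trials.n_censored
    m0, s0, ll_gauss = _gauss_max_loglik(p)
    jac = _jacobian_term(p)

    if censoring == "exclude" or n_cens == 0:
        return FitResult(
            params=RecinormalParams(m=m0, s=s0),
            log_likelihood=ll_gauss + jac,
            n_used=len(p),
            n_censored=n_cens,
            converged=True,
        )
    if censoring != "likelihood":
        raise DomainError(f"unknown censoring mode {censoring!r}")

    w = window_ms / 1000.0  # seconds

    def nll(theta: np.ndarray) -> float:
        m, log_s = theta
        s = np.exp(log_s)
        ll = _gauss_loglik(p, m, s)
        ll += n_cens * norm.logcdf((1.0 / w - m) / s)
        return -ll

    res = optimize.minimize(nll, x0=np.array([m0, np.log(s0)]), method="Nelder-Mead")
    m_hat, s_hat = float(res.x[0]), float(np.exp(res.x[1]))
    return FitResult(
        params=RecinormalParams(m=m_hat, s=s_hat),
        log_likelihood=float(-res.fun) + jac,
        n_used=len(p),
        n_censored=n_cens,
        converged=bool(res.success),
    )


def fit_early_mixture(
    trials: TrialSet,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> FitResult:
    """EM fit of the main + early promptness mixture.

    The early component is constrained to zero mean (its reciprobit line is
    its slope ``sigma_prime`` alone); the main component is a free Gaussian
    ``(m, s)``.  Initialization is deterministic: moments of the sample for
    the main component, ``sigma_prime = 3 * s``, weight 0.1.  If EM ends
    below the single-component likelihood (possible under truncation of
    the early mass), the weight-zero solution is returned with a boundary
    flag, so the mixture likelihood is never below the single-component
    one.  Censored trials are excluded.
    """
    p = _promptness(trials, 10)
    n = len(p)
    m, s, ll_single = _gauss_max_loglik(p)
    jac = _jacobian_term(p)

    sigma_prime = 3.0 * s
    pi = 0.1
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        dens_early = pi * norm.pdf(p, 0.0, sigma_prime)
        dens_main = (1.0 - pi) * norm.pdf(p, m, s)
        total = dens_early + dens_main
        total = np.where(total > 0, total, np.finfo(float).tiny)
        ll = float(np.sum(np.log(total)))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        gamma = dens_early / total
        pi = float(np.mean(gamma))
        w_main = 1.0 - gamma
        sw = float(np.sum(w_main))
        if sw < 1e-12 or pi >= 1.0 - 1e-12:
            break  # all mass on the early component: degenerate
        m = float(np.sum(w_main * p) / sw)
        s = max(float(np.sqrt(np.sum(w_main * (p - m) ** 2) / sw)), 1e-10)
        sg = float(np.sum(gamma))
        if sg > 1e-12:
            sigma_prime = max(float(np.sqrt(np.sum(gamma * p**2) / sg)), 1e-10)

    if ll_old < ll_single or not np.isfinite(ll_old):
        # EM trapped below the nested single-component optimum: report the
        # pi = 0 boundary solution, whose likelihood equals the single fit.
        return FitResult(
            params=RecinormalParams(m=float(np.mean(p)), s=float(np.std(p))),
            log_likelihood=ll_single + jac,
            n_used=n,
            n_censored=trials.n_censored,
            converged=True,
            early=EarlyComponent(sigma_prime=sigma_prime, weight=0.0),
            boundary=True,
        )
    return FitResult(
        params=RecinormalParams(m=m, s=s),
        log_likelihood=ll_old + jac,
        n_used=n,
        n_censored=trials.n_censored,
        converged=converged,
        early=EarlyComponent(sigma_prime=sigma_prime, weight=pi),
        boundary=bool(pi < 1e-3 or pi > 1.0 - 1e-3),
    )


PlottingRule = Literal["weibull", "blom"]


def reciprobit_coordinates(
    trials: TrialSet, plotting_position: PlottingRule = "weibull"
) -> np.ndarray:
    """Empirical reciprobit coordinates of the non-censored trials.

    Returns an ``(n, 2)`` array of ``(promptness, probit)`` pairs sorted by
    ascending latency.  The x value is promptness itself (1/s); rendering
    it on a reversed axis is a plotting concern.  Cumulative probabilities
    use the ``k/(n+1)`` rule by default or Blom's ``(k-0.375)/(n+0.25)``.
    """
    lat = np.sort(trials.latencies_ms)
    n = len(lat)
    if n < 2:
        raise InsufficientDataError("need at least 2 non-censored trials to plot")
    k = np.arange(1, n + 1)
    if plotting_position == "weibull":
        q = k / (n + 1.0)
    elif plotting_position == "blom":
        q = (k - 0.375) / (n + 0.25)
    else:
        raise DomainError(f"unknown plotting position rule {plotting_position!r}")
    return np.column_stack([1000.0 / lat, norm.ppf(q)])


def _swivel_scale(k: float, n: int, sum_p: float, sum_p2: float) -> float:
    """Per-condition ML scale under the common-intercept constraint m = k*s.

    Stationarity of the Gaussian likelihood in s gives the quadratic
    ``n s**2 + k B s - A = 0`` (B = sum p, A = sum p**2), whose positive
    root is the ML scale for the given k.
    """
    disc = k * k * sum_p * sum_p + 4.0 * n * sum_p2
    return (-k * sum_p + np.sqrt(disc)) / (2.0 * n)


def _swivel_loglik(k: float, pa: np.ndarray, pb: np.ndarray) -> tuple[float, float, float]:
    ll = 0.0
    scales = []
    for p in (pa, pb):
        s_g = _swivel_scale(k, len(p), float(np.sum(p)), float(np.sum(p * p)))
        if s_g <= 0 or not np.isfinite(s_g):
            return -np.inf, np.nan, np.nan
        ll += _gauss_loglik(p, k * s_g, s_g)
        scales.append(s_g)
    return ll, scales[0], scales[1]


def _fit_swivel(pa: np.ndarray, pb: np.ndarray) -> HypothesisFit:
    """Common infinite-time intercept, free slopes: maximize over the shared
    ratio k = m/s with the per-condition scales profiled out in closed form."""
    pooled = np.concatenate([pa, pb])
    k_candidates = [
        float(np.mean(p) / np.std(p)) for p in (pa, pb, pooled) if np.std(p) > 0
    ]
    k_lo = min(k_candidates) - 5.0
    k_hi = max(k_candidates) + 5.0
    res = optimize.minimize_scalar(
        lambda k: -_swivel_loglik(k, pa, pb)[0],
        bounds=(k_lo, k_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best_k = float(res.x)
    best_ll, sa, sb = _swivel_loglik(best_k, pa, pb)
    for k in k_candidates:  # guards the nesting LL(same) <= LL(swivel)
        ll, s1, s2 = _swivel_loglik(k, pa, pb)
        if ll > best_ll:
            best_k, best_ll, sa, sb = k, ll, s1, s2
    return HypothesisFit(
        a=RecinormalParams(m=best_k * sa, s=sa),
        b=RecinormalParams(m=best_k * sb, s=sb),
        log_likelihood=best_ll,
        n_free=3,
    )


def compare_conditions(
    a: TrialSet,
    b: TrialSet,
    alpha: float = 0.05,
    correction: Literal["bonferroni"] | None = None,
) -> ConditionComparison:
    """Classify a between-condition change as swivel, shift, full or none.

    Fits the four nested promptness hypotheses by (constrained) maximum
    likelihood on the non-censored trials and applies the decision tree
    described in the module docstring.  ``correction="bonferroni"`` halves
    alpha for the two second-stage tests; by default the two planned
    comparisons are interpreted jointly at the nominal level.
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    pa = _promptness(a, 3)
    pb = _promptness(b, 3)
    pooled = np.concatenate([pa, pb])
    jac = _jacobian_term(pooled)

    m_a, s_a, ll_a = _gauss_max_loglik(pa)
    m_b, s_b, ll_b = _gauss_max_loglik(pb)
    full = HypothesisFit(
        a=RecinormalParams(m=m_a, s=s_a),
        b=RecinormalParams(m=m_b, s=s_b),
        log_likelihood=ll_a + ll_b,
        n_free=4,
    )
    m_p, s_p, ll_p = _gauss_max_loglik(pooled)
    same_params = RecinormalParams(m=m_p, s=s_p)
    same = HypothesisFit(a=same_params, b=same_params, log_likelihood=ll_p, n_free=2)
    # Common slope, free means: pooled ML variance about per-condition means.
    s_shift = float(
        np.sqrt(
            (np.sum((pa - m_a) ** 2) + np.sum((pb - m_b) ** 2)) / (len(pa) + len(pb))
        )
    )
    if s_shift <= 0:
        raise FitError("degenerate data: zero within-condition variance")
    shift = HypothesisFit(
        a=RecinormalParams(m=m_a, s=s_shift),
        b=RecinormalParams(m=m_b, s=s_shift),
        log_likelihood=_gauss_loglik(pa, m_a, s_shift)
        + _gauss_loglik(pb, m_b, s_shift),
        n_free=3,
    )
    swivel = _fit_swivel(pa, pb)

    fits = {
        name: HypothesisFit(f.a, f.b, f.log_likelihood + jac, f.n_free)
        for name, f in
        {"same": same, "swivel": swivel, "shift": shift, "full": full}.items()
    }

    stats: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for name, df in (("same", 2), ("swivel", 1), ("shift", 1)):
        d = max(2.0 * (fits["full"].log_likelihood - fits[name].log_likelihood), 0.0)
        stats[name] = d
        p_values[name] = float(chi2.sf(d, df))

    alpha2 = alpha / 2.0 if correction == "bonferroni" else alpha
    if p_values["same"] >= alpha:
        verdict = "none"
    else:
        ok_swivel = p_values["swivel"] >= alpha2
        ok_shift = p_values["shift"] >= alpha2
        if ok_swivel and ok_shift:
            verdict = (
                "swivel"
                if fits["swivel"].log_likelihood >= fits["shift"].log_likelihood
                else "shift"
            )
        elif ok_swivel:
            verdict = "swivel"
        elif ok_shift:
            verdict = "shift"
        else:
            verdict = "full"
    return ConditionComparison(
        fits=fits,
        statistics=stats,
        p_values=p_values,
        verdict=verdict,
        alpha=alpha,
        correction=correction,
    )


def classify_latency(latency_ms, bins: LatencyClassBins = DEFAULT_BINS):
    """Histogram class of a latency in ms (scalar or array)."""
    lat = np.asarray(latency_ms, dtype=float)
    if np.any(lat <= 0):
        raise DomainError("latency must be positive")
    idx = np.searchsorted(np.asarray(bins.boundaries_ms), lat, side="right")
    labels = np.asarray(bins.labels, dtype=object)[idx]
    if lat.ndim == 0:
        return str(labels)
    return labels


def bin_proportions(trials: TrialSet, bins: LatencyClassBins = DEFAULT_BINS):
    """Proportion of non-censored trials in each latency class (sums to 1)."""
    import pandas as pd

    lat = trials.latencies_ms
    if len(lat) == 0:
        raise InsufficientDataError("no non-censored trials to bin")
    labels = classify_latency(lat, bins)
    counts = pd.Series(labels).value_counts()
    props = counts.reindex(bins.labels, fill_value=0) / len(lat)
    props.index.name = "latency_class"
    return props


def bootstrap_ci(
    trials: TrialSet,
    statistic: Callable[[TrialSet], float],
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for a TrialSet statistic.

    Resamples whole trial records (censored ones included) with
    replacement.  With fewer than 100 resamples a warning is logged and the
    interval is still computed.
    """
    if n_boot < 1:
        raise DomainError("n_boot must be >= 1")
    if n_boot < 100:
        logger.warning("bootstrap with n_boot=%d < 100 resamples is unstable", n_boot)
    if not 0.0 < level < 1.0:
        raise DomainError(f"level must lie in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    n = len(trials)
    values = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resample = TrialSet(trials.data.iloc[idx].reset_index(drop=True))
        values[i] = statistic(resample)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(values, lo)),
        float(np.quantile(values, 1.0 - lo)),
    )
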