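"""MaxSPRT sequential testing: log-likelihood ratios and critical values.

Surveillance re-tests the same hypothesis every calendar month on the
accumulated data. MaxSPRT controls the overall alpha by comparing, at each
look, the log-likelihood ratio (LLR) of the maximum-likelihood alternative
against a flat critical value chosen so that the probability under the null
of ever crossing it across the whole look schedule is at most alpha.

Two data models are used, matching how each design summarises its evidence:

* Poisson (historical comparator): observed count ``c`` against an expected
  count ``u`` derived from the historic rate.
* Binomial (all other designs): of ``n`` total events, ``c`` fell in the
  risk window, against the null proportion ``1/(1+z)`` where ``z`` is the
  control-to-risk person-time ratio.

Critical values are computed by seeded Monte-Carlo simulation of null data
over the look schedule; the single-look Poisson case has an exact tail-sum
check used in the tests. Designs that only yield (log estimate, SE) use the
normal-approximation LLR ``theta^2 / (2 SE^2)`` for positive estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LookSchedule",
    "CriticalValue",
    "poisson_llr",
    "binomial_llr",
    "normal_llr",
    "critical_value",
    "sequential_signal",
]


@dataclass(frozen=True)
class LookSchedule:
    """Cumulative null information at each monthly look.

    ``expected`` holds cumulative expected counts (Poisson model) or
    cumulative total event counts (binomial model); ``z`` the per-look
    control-to-risk time ratio (binomial only).
    """

    model: str  # "poisson" | "binomial" | "normal"
    expected: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self):
        exp = np.asarray(self.expected, dtype=float)
        object.__setattr__(self, "expected", exp)
        if self.model not in ("poisson", "binomial", "normal"):
            raise ValueError(f"unknown model {self.model!r}")
        if np.any(np.diff(exp) < -1e-9):
            raise ValueError("cumulative expected counts must be non-decreasing")
        if self.model == "binomial":
            z = np.broadcast_to(np.asarray(self.z, dtype=float), exp.shape).copy()
            if np.any(z <= 0):
                raise ValueError("time ratio z must be positive")
            object.__setattr__(self, "z", z)


@dataclass(frozen=True)
class CriticalValue:
    value: float
    model: str
    alpha: float
    attained_alpha: float


def poisson_llr(c, u):
    """Poisson MaxSPRT LLR: c ln(c/u) - (c - u) when c > u, else 0."""
    c = np.asarray(c, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("expected count u must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        llr = np.where(c > u, c * np.log(np.where(c > 0, c / u, 1.0)) - (c - u), 0.0)
    return llr if llr.ndim else float(llr)


def binomial_llr(c, n, z):
    """Binomial MaxSPRT LLR against null proportion 1/(1+z).

    ``c`` of ``n`` events in the risk window, with control-to-risk time ratio
    ``z``; one-sided, 0 on or below the null proportion; 0 ln 0 = 0.
    """
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("time ratio z must be positive")
    if np.any((c < 0) | (c > n)):
        raise ValueError("need 0 <= c <= n")
    p0 = 1.0 / (1.0 + z)
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = np.where(n > 0, c / np.where(n > 0, n, 1.0), 0.0)
        t1 = np.where(c > 0, c * np.log(phat / p0), 0.0)
        t2 = np.where(n - c > 0, (n - c) * np.log((1 - phat) / (1 - p0)), 0.0)
        llr = np.where((n > 0) & (phat > p0), t1 + t2, 0.0)
    return llr if llr.ndim else float(llr)


def normal_llr(log_estimate, se):
    """Normal-approximation LLR for designs summarised by (estimate, SE)."""
    theta = np.asarray(log_estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    llr = np.where(theta > 0, theta**2 / (2 * se**2), 0.0)
    return llr if llr.ndim else float(llr)


def _null_max_llrs(schedule: LookSchedule, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Per-replicate maximum LLR over the looks under the null."""
    exp = schedule.expected
    incr = np.diff(np.r_[0.0, exp])
    if exp[-1] <= 0:
        raise ValueError("schedule carries no information")
    if schedule.model == "poisson":
        counts = np.cumsum(rng.poisson(incr, size=(reps, len(incr))), axis=1)
        llrs = poisson_llr(counts, np.maximum(exp, 1e-300))
        llrs[:, exp <= 0] = 0.0
    elif schedule.model == "normal":
        # expected = cumulative Fisher information; the score process under
        # the null is Brownian in information time
        w = np.cumsum(
            rng.normal(0.0, 1.0, size=(reps, len(incr))) * np.sqrt(np.maximum(incr, 0.0)),
            axis=1,
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            z = w / np.sqrt(np.maximum(exp, 1e-300))
        llrs = np.where(z > 0, z**2 / 2.0, 0.0)
        llrs[:, exp <= 0] = 0.0
    else:
        p0 = 1.0 / (1.0 + schedule.z)
        # per-look increments allocated to the risk window at that look's null rate
        c_inc = rng.binomial(incr.astype(int), p0, size=(reps, len(incr)))
        counts = np.cumsum(c_inc, axis=1)
        llrs = binomial_llr(counts, np.maximum(exp, 1.0), schedule.z)
        llrs[:, exp <= 0] = 0.0
    return llrs.max(axis=1)


def critical_value(
    schedule: LookSchedule,
    alpha: float = 0.05,
    mc_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> CriticalValue:
    """Flat LLR boundary with any-look null crossing probability <= alpha.

    The boundary is the ceil((1-alpha) * mc_reps)-th order statistic of the
    per-replicate maximum null LLR, so that strictly exceeding it happens in
    at most an alpha fraction of null replicates; the attained (Monte-Carlo)
    alpha is reported alongside.
    """
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must lie in (0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_llrs = np.sort(_null_max_llrs(schedule, mc_reps, rng))
    k = int(np.ceil((1 - alpha) * mc_reps)) - 1
    cv = float(max_llrs[k])
    attained = float(np.mean(max_llrs > cv))
    return CriticalValue(cv, schedule.model, alpha, attained)


def sequential_signal(llrs, cv: float) -> int | None:
    """Earliest 1-based look whose LLR exceeds the critical value, else None."""
    llrs = np.asarray(llrs, dtype=float)
    above = np.flatnonzero(llrs > cv)
    return int(above[0]) + 1 if len(above) else None
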