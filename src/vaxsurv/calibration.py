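"""Empirical calibration of p-values and LLRs using negative controls.

Observational designs carry systematic error (confounding, selection,
measurement) that the nominal standard error ignores. Following the
negative-control calibration approach, the log estimates of outcomes with
true rate ratio 1 are modelled as

    theta_i ~ Normal(beta_i, se_i^2),   beta_i ~ Normal(mu, tau^2),

so the marginal likelihood of each negative-control estimate is
Normal(mu, tau^2 + se_i^2). The fitted (mu, tau) describe the systematic
error; calibrated one-sided p-values and LLRs are then computed against this
shifted, widened null. With (mu, tau) = (0, 0) calibration is the identity.

For evaluation, each control outcome is calibrated leave-one-out: against
the distribution fitted on all other controls, so its own estimate never
informs its calibration. Imputed positive controls (a negative control's
estimate multiplied by a known factor) are calibrated against the fit that
excludes their parent negative control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NullDistribution",
    "fit_null",
    "calibrate_p",
    "calibrate_llr",
    "impute_positive",
    "loo_calibrate",
    "bootstrap_null",
]


@dataclass(frozen=True)
class NullDistribution:
    """Gaussian systematic-error model on the log scale."""

    mu: float
    tau: float
    n_controls: int
    converged: bool = True


def _profile_mu(tau: float, theta: np.ndarray, se: np.ndarray) -> float:
    w = 1.0 / (tau**2 + se**2)
    return float(np.sum(w * theta) / np.sum(w))


def _neg_loglik(tau: float, theta: np.ndarray, se: np.ndarray) -> float:
    var = tau**2 + se**2
    mu = _profile_mu(tau, theta, se)
    return float(0.5 * np.sum(np.log(2 * np.pi * var) + (theta - mu) ** 2 / var))


def fit_null(theta_hat, se) -> NullDistribution:
    """Maximum-likelihood (mu, tau >= 0) from negative-control estimates.

    mu is profiled out in closed form (precision-weighted mean), leaving a
    one-dimensional likelihood in tau that is maximised on a coarse grid and
    refined locally — cheap and robust to the flat boundary at tau = 0.
    """
    theta = np.asarray(theta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    ok = np.isfinite(theta) & np.isfinite(se) & (se > 0)
    theta, se = theta[ok], se[ok]
    if len(theta) < 2:
        raise ValueError("need at least 2 estimable negative-control estimates")

    tau_hi = max(2.0 * np.std(theta), 0.1)
    grid = np.linspace(0.0, tau_hi, 41)
    vals = [_neg_loglik(t, theta, se) for t in grid]
    t0 = grid[int(np.argmin(vals))]
    lo = max(t0 - tau_hi / 40, 0.0)
    hi = min(t0 + tau_hi / 40, tau_hi)
    res = optimize.minimize_scalar(
        _neg_loglik, bounds=(lo, hi), args=(theta, se), method="bounded",
        options={"xatol": 1e-10},
    )
    tau = float(res.x) if res.fun <= min(vals) + 1e-9 else float(t0)
    converged = bool(res.success)
    if _neg_loglik(0.0, theta, se) <= _neg_loglik(tau, theta, se):
        tau = 0.0
    mu = _profile_mu(tau, theta, se)
    return NullDistribution(mu=mu, tau=tau, n_controls=len(theta), converged=converged)


def calibrate_p(theta_hat, se, null: NullDistribution):
    """Calibrated one-sided upper p-value against the systematic-error null."""
    theta = np.asarray(theta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    p = stats.norm.sf((theta - null.mu) / np.sqrt(null.tau**2 + se**2))
    return p if p.ndim else float(p)


def calibrate_llr(theta_hat, se, null: NullDistribution):
    """Calibrated LLR: (theta - mu)^2 / (2 (tau^2 + se^2)) for theta > mu, else 0."""
    theta = np.asarray(theta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    llr = np.where(theta > null.mu, (theta - null.mu) ** 2 / (2 * (null.tau**2 + se**2)), 0.0)
    return llr if llr.ndim else float(llr)


def impute_positive(record: dict | pd.Series, k: float) -> dict:
    """Impute a positive control by multiplying the estimate by k (> 1).

    The log estimate is shifted by ln k; the SE and supporting counts are
    carried over unchanged, encoding the assumption that systematic error
    does not change with the true effect size.
    """
    if k <= 1:
        raise ValueError("imputation factor k must exceed 1")
    rec = dict(record if isinstance(record, dict) else record.to_dict())
    if not rec.get("estimable", False):
        raise ValueError("cannot impute a positive from a non-estimable record")
    rec["log_estimate"] = rec["log_estimate"] + np.log(k)
    rec["ci_lower"] = rec["ci_lower"] * k if np.isfinite(rec.get("ci_lower", np.nan)) else np.nan
    rec["ci_upper"] = rec["ci_upper"] * k if np.isfinite(rec.get("ci_upper", np.nan)) else np.nan
    rec["true_effect_size"] = float(k)
    # the p-value must reflect the shifted estimate (normal approximation on
    # the log scale with the carried-over SE)
    rec["p_one_sided"] = float(stats.norm.sf(rec["log_estimate"] / rec["se"]))
    return rec


def loo_calibrate(estimates: pd.DataFrame, parent_col: str = "outcome_id") -> pd.DataFrame:
    """Leave-one-out calibration of one (design, variant, look) cell.

    ``estimates`` holds the negative-control rows (``true_effect_size == 1``)
    and any imputed positives; positives must carry their parent negative
    control's id in ``parent_col``. Each control is calibrated against the
    systematic-error fit on all *other* negatives' estimable estimates.
    Adds/overwrites ``p_calibrated`` and ``llr_calibrated``.
    """
    est = estimates.copy()
    negatives = est[(est["true_effect_size"] == 1.0) & (est["estimable"] == True)]  # noqa: E712
    ids = negatives[parent_col].to_numpy()
    theta = negatives["log_estimate"].to_numpy(dtype=float)
    se = negatives["se"].to_numpy(dtype=float)
    if len(negatives) < 3:
        raise ValueError("leave-one-out calibration needs >= 3 estimable negatives")

    p_cal = np.full(len(est), np.nan)
    llr_cal = np.full(len(est), np.nan)
    parents = est[parent_col].to_numpy()
    for parent in np.unique(parents):
        mask = ids != parent
        null = fit_null(theta[mask], se[mask])
        rows = np.flatnonzero((parents == parent) & est["estimable"].to_numpy())
        th = est["log_estimate"].to_numpy(dtype=float)[rows]
        s = est["se"].to_numpy(dtype=float)[rows]
        p_cal[rows] = np.atleast_1d(calibrate_p(th, s, null))
        llr_cal[rows] = np.atleast_1d(calibrate_llr(th, s, null))
    est["p_calibrated"] = p_cal
    est["llr_calibrated"] = llr_cal
    return est


def bootstrap_null(theta_hat, se, n_boot: int = 500, seed: int = 0) -> pd.DataFrame:
    """Nonparametric bootstrap (over controls) of the (mu, tau) fit.

    Used for the credible-band shading in the systematic-error plots.
    """
    theta = np.asarray(theta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(theta), len(theta))
        if len(np.unique(idx)) < 2:
            continue
        fit = fit_null(theta[idx], se[idx])
        out.append((fit.mu, fit.tau))
    return pd.DataFrame(out, columns=["mu", "tau"])
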