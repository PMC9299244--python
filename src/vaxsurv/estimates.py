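"""Shared schema for design-variant estimates.

Every design emits one row per (design, variant, outcome, look) with the
log effect estimate, its standard error, 95% CI on the ratio scale, the
one-sided upper p-value, MaxSPRT log-likelihood ratio and critical value,
their empirically calibrated twins, and design-specific supporting counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ESTIMATE_COLUMNS = [
    "design",
    "variant",
    "outcome_id",
    "true_effect_size",
    "look_month",
    "log_estimate",
    "se",
    "ci_lower",
    "ci_upper",
    "p_one_sided",
    "llr",
    "cv",
    "p_calibrated",
    "llr_calibrated",
    "events_exposed",
    "events_comparator",
    "expected",
    "exposed_time",
    "comparator_time",
    "estimable",
]


def make_record(**kwargs) -> dict:
    """One estimate row; unset fields default to NaN (``estimable`` to False)."""
    rec = {c: np.nan for c in ESTIMATE_COLUMNS}
    rec["estimable"] = False
    unknown = set(kwargs) - set(ESTIMATE_COLUMNS)
    if unknown:
        raise TypeError(f"unknown estimate fields: {sorted(unknown)}")
    rec.update(kwargs)
    return rec


def records_frame(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records, columns=ESTIMATE_COLUMNS)


def wald_fields(log_est: float, se: float) -> dict:
    """CI (ratio scale) and one-sided upper p from a log estimate and its SE."""
    z = log_est / se
    return {
        "log_estimate": log_est,
        "se": se,
        "ci_lower": float(np.exp(log_est - 1.96 * se)),
        "ci_upper": float(np.exp(log_est + 1.96 * se)),
        "p_one_sided": float(stats.norm.sf(z)),
        "estimable": True,
    }
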