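"""Self-controlled designs: SCCS and SCRI.

Both designs compare each vaccinated person's event rate in the 1-28 day
time-at-risk window against that same person's unexposed time, conditioning
on the person's total event count. Between-person differences (frailty,
care-seeking) cancel exactly, which is why these designs resist the
unmeasured confounding that breaks the between-person comparisons.

Five variants:

* ``sccs``: control time is all observed in-study time, excluding the 30
  days before each vaccination (people are less likely to be vaccinated
  right after a serious outcome);
* ``sccs_age_season``: as above, with cubic-spline adjustment for age and
  season (5 equally spaced knots each);
* ``scri_pre``: control interval fixed at days -43..-15 before vaccination;
* ``scri_post``: control interval fixed at days +43..+71 after vaccination;
* ``sccs_all_pre``: all pre-vaccination time excluded, control is all
  observed time after the time-at-risk window.

The SCCS likelihood is the conditional Poisson (multinomial) likelihood:
within a person, events distribute across that person's intervals with
probabilities proportional to interval length x exp(x'beta). It is
maximised by Newton iteration with analytic gradient and Hessian. The SCRI
estimate uses the conditional binomial: given the total event count in risk
plus control intervals, the risk-window count is binomial with null
proportion L_risk / (L_risk + L_control), giving an exact
(Clopper-Pearson) interval for the incidence rate ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from ._dates import DAYS_PER_YEAR
from .estimates import make_record, wald_fields
from .synthetic_data import EventTables, SimulationConfig

__all__ = [
    "build_intervals",
    "fit_sccs",
    "fit_scri",
    "run_self_controlled",
    "SELF_CONTROLLED_VARIANTS",
]

SELF_CONTROLLED_VARIANTS = [
    "sccs",
    "sccs_age_season",
    "scri_pre",
    "scri_post",
    "sccs_all_pre",
]

RISK, CONTROL, EXCLUDED = 2, 1, 0  # precedence: risk > excluded > control

PRE_EXCLUSION_DAYS = 30
SCRI_PRE_WINDOW = (-43, -15)
SCRI_POST_WINDOW = (43, 71)


def build_intervals(
    vaccinations: pd.DataFrame,
    periods: pd.DataFrame,
    config: SimulationConfig,
    variant: str,
    look_cutoff: int,
    person_ids=None,
) -> pd.DataFrame:
    """Person-interval sets for one variant: columns person_id, start, end, status.

    Intervals are clipped to observation period ∩ study period ∩ cutoff.
    Overlaps (e.g. two doses 28 days apart) resolve risk > excluded >
    control; excluded time is dropped from the output. Persons whose control
    time is fully clipped away simply emit no control rows and are dropped by
    the fitters.
    """
    if variant not in SELF_CONTROLLED_VARIANTS:
        raise ValueError(f"unknown self-controlled variant {variant!r}")
    ss, se = config.study_window
    hi_all = min(se, look_cutoff)
    vacc = vaccinations[vaccinations["date"] <= look_cutoff]
    if person_ids is not None:
        vacc = vacc[vacc["person_id"].isin(person_ids)]
    per = periods.set_index("person_id")

    rows: list[tuple] = []
    for pid, g in vacc.groupby("person_id"):
        lo = max(int(per.loc[pid, "start"]), ss)
        hi = min(int(per.loc[pid, "end"]), hi_all)
        if lo > hi:
            continue
        n_days = hi - lo + 1
        label = np.full(n_days, CONTROL if variant.startswith("sccs") else EXCLUDED, dtype=np.int8)
        doses = np.sort(g["date"].to_numpy())

        def paint(a: int, b: int, status: int) -> None:
            a, b = max(a, lo), min(b, hi)
            if a > b:
                return
            seg = label[a - lo : b - lo + 1]
            if status == RISK:
                seg[:] = RISK
            elif status == EXCLUDED:
                seg[seg != RISK] = EXCLUDED
            else:  # control paints over excluded-by-default only
                seg[(seg != RISK)] = CONTROL

        if variant == "sccs_all_pre":
            paint(lo, int(doses[0]) + config.tar_start_day - 1, EXCLUDED)
        for v in doses:
            v = int(v)
            if variant in ("sccs", "sccs_age_season"):
                paint(v - PRE_EXCLUSION_DAYS, v + config.tar_start_day - 1, EXCLUDED)
            elif variant == "scri_pre":
                paint(v + SCRI_PRE_WINDOW[0], v + SCRI_PRE_WINDOW[1], CONTROL)
            elif variant == "scri_post":
                paint(v + SCRI_POST_WINDOW[0], v + SCRI_POST_WINDOW[1], CONTROL)
        for v in doses:  # risk wins over everything
            v = int(v)
            paint(v + config.tar_start_day, v + config.tar_end_day, RISK)

        # run-length encode non-excluded stretches
        change = np.flatnonzero(np.diff(label)) + 1
        starts = np.r_[0, change]
        ends = np.r_[change, n_days]
        for a, b in zip(starts, ends):
            if label[a] != EXCLUDED:
                rows.append((pid, lo + int(a), lo + int(b) - 1, "risk" if label[a] == RISK else "control"))

    return pd.DataFrame(rows, columns=["person_id", "start", "end", "status"])


def _split_by_month(intervals: pd.DataFrame, month_end_days: np.ndarray) -> pd.DataFrame:
    """Split intervals at calendar-month boundaries (for age/season terms)."""
    bounds = np.asarray(month_end_days)
    out = []
    for _, r in intervals.iterrows():
        cuts = bounds[(bounds >= r["start"]) & (bounds < r["end"])]
        edges = np.r_[r["start"], cuts + 1]
        ends = np.r_[cuts, r["end"]]
        for a, b in zip(edges, ends):
            out.append((r["person_id"], int(a), int(b), r["status"]))
    return pd.DataFrame(out, columns=["person_id", "start", "end", "status"])


def _spline_basis(x: np.ndarray, n_knots: int = 5) -> np.ndarray:
    """Cubic B-spline basis with ``n_knots`` equally spaced knots spanning x.

    The first column is dropped (absorbed by the per-person conditioning).
    Degenerate inputs (near-constant x) return an empty basis.
    """
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-9:
        return np.empty((len(x), 0))
    knots = np.linspace(lo, hi, n_knots)
    t = np.r_[[lo] * 3, knots, [hi] * 3]
    basis = BSpline.design_matrix(np.clip(x, lo, hi), t, 3).toarray()
    return basis[:, 1:]


def _conditional_poisson(
    y: np.ndarray,
    X: np.ndarray,
    log_t: np.ndarray,
    groups: np.ndarray,
    penalty: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton fit of the within-person multinomial likelihood.

    Rows must be sorted by group. ``penalty`` holds a per-coefficient ridge
    term (the conditioning leaves spline adjustment directions only weakly
    identified, so those columns carry a small ridge while the exposure
    coefficient is essentially unpenalised). Returns (beta, covariance,
    converged).
    """
    order = np.argsort(groups, kind="stable")
    y, X, log_t, groups = y[order], X[order], log_t[order], groups[order]
    starts = np.r_[0, np.flatnonzero(np.diff(groups)) + 1]
    n_g = np.add.reduceat(y, starts)

    p_dim = X.shape[1]
    if penalty is None:
        penalty = np.full(p_dim, 1e-8)
    ridge = np.asarray(penalty, dtype=float)
    counts = np.diff(np.r_[starts, len(y)])

    def _parts(b):
        eta = log_t + X @ b
        gmax = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - np.repeat(gmax, counts))
        denom = np.add.reduceat(w, starts)
        ll = float(y @ eta - n_g @ (np.log(denom) + gmax) - 0.5 * (ridge * b**2).sum())
        p = w / np.repeat(denom, counts)
        return ll, p

    beta = np.zeros(p_dim)
    converged = False
    ll, p = _parts(beta)
    for _ in range(100):
        resid = y - np.repeat(n_g, counts) * p
        grad = X.T @ resid - ridge * beta
        # Hessian: sum_g n_g (X' diag(p) X - m m'), m = X' p per group
        M = np.add.reduceat(X * p[:, None], starts, axis=0)  # per-group X'p
        H = (X * (np.repeat(n_g, counts) * p)[:, None]).T @ X
        H -= (M * n_g[:, None]).T @ M
        H += np.diag(ridge)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # backtracking line search on the penalised log-likelihood
        for _halve in range(40):
            ll_new, p_new = _parts(beta + step)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll, p = ll_new, p_new
        if np.max(np.abs(grad)) < 1e-8 * max(1.0, n_g.sum()) or np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p_dim, p_dim), np.nan)
    return beta, cov, converged


def _interval_frame(
    intervals: pd.DataFrame, events: pd.DataFrame, look_cutoff: int
) -> pd.DataFrame:
    """Attach event counts (first occurrences) to intervals."""
    iv = intervals.copy()
    iv["length"] = iv["end"] - iv["start"] + 1
    iv["y"] = 0
    ev = events[events["date"] <= look_cutoff]
    if len(ev):
        merged = ev.merge(iv.reset_index(), on="person_id", how="inner")
        hit = merged[(merged["date"] >= merged["start"]) & (merged["date"] <= merged["end"])]
        counts = hit.groupby("index").size()
        iv.loc[counts.index, "y"] = counts.to_numpy()
    return iv


def fit_sccs(
    intervals: pd.DataFrame,
    events: pd.DataFrame,
    config: SimulationConfig,
    adjust: bool = False,
    look_cutoff: int | None = None,
    persons: pd.DataFrame | None = None,
) -> dict:
    """Conditional Poisson SCCS estimate from interval sets and event dates.

    ``events`` has columns person_id, date (first occurrences of one
    outcome). With ``adjust`` the intervals are split by calendar month and
    cubic-spline terms in age and season (day of study) enter the linear
    predictor alongside the exposure indicator.
    """
    if look_cutoff is None:
        look_cutoff = config.study_window[1]
    if adjust:
        from ._dates import month_ends

        intervals = _split_by_month(intervals, month_ends(*config.study_window))
    iv = _interval_frame(intervals, events, look_cutoff)

    # only persons with >= 1 event contribute to the conditional likelihood
    per_events = iv.groupby("person_id")["y"].sum()
    keep = per_events[per_events > 0].index
    iv = iv[iv["person_id"].isin(keep)]

    risk_days = int(iv.loc[iv["status"] == "risk", "length"].sum())
    control_days = int(iv.loc[iv["status"] == "control", "length"].sum())
    c_risk = int(iv.loc[iv["status"] == "risk", "y"].sum())
    c_control = int(iv.loc[iv["status"] == "control", "y"].sum())
    base = dict(
        events_exposed=c_risk,
        events_comparator=c_control,
        exposed_time=risk_days / DAYS_PER_YEAR,
        comparator_time=control_days / DAYS_PER_YEAR,
    )
    if len(iv) == 0 or c_risk + c_control == 0 or risk_days == 0 or control_days == 0:
        return make_record(estimable=False, **base)
    if c_risk == 0 or (c_control == 0 and not adjust):
        # monotone likelihood: estimate at the boundary
        return make_record(estimable=False, **base)

    x_cols = [(iv["status"] == "risk").to_numpy(dtype=float)]
    if adjust and persons is not None:
        mid = (iv["start"].to_numpy() + iv["end"].to_numpy()) / 2.0
        birth = persons.set_index("person_id").loc[iv["person_id"], "birth_date"].to_numpy()
        age = (mid - birth) / DAYS_PER_YEAR
        season = mid - config.study_window[0]
        x_cols += [_spline_basis(age), _spline_basis(season)]
        X = np.column_stack(x_cols)
    else:
        X = x_cols[0][:, None]

    penalty = np.full(X.shape[1], 1e-2)
    penalty[0] = 1e-8
    beta, cov, converged = _conditional_poisson(
        iv["y"].to_numpy(dtype=float),
        X,
        np.log(iv["length"].to_numpy(dtype=float)),
        iv["person_id"].to_numpy(),
        penalty=penalty,
    )
    se = float(np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else np.nan
    if not converged or not np.isfinite(se) or abs(beta[0]) > 10:
        return make_record(estimable=False, **base)
    return make_record(**wald_fields(float(beta[0]), se), **base)


def fit_scri(
    intervals: pd.DataFrame,
    events: pd.DataFrame,
    config: SimulationConfig,
    look_cutoff: int | None = None,
) -> dict:
    """Conditional binomial SCRI estimate with exact Clopper-Pearson interval.

    Events outside both intervals never enter; the incidence rate ratio is
    (c_risk / L_risk) / (c_control / L_control) on pooled interval lengths.
    """
    if look_cutoff is None:
        look_cutoff = config.study_window[1]
    iv = _interval_frame(intervals, events, look_cutoff)
    per_events = iv.groupby("person_id")["y"].sum()
    keep = per_events[per_events > 0].index
    iv = iv[iv["person_id"].isin(keep)]

    risk = iv[iv["status"] == "risk"]
    ctl = iv[iv["status"] == "control"]
    c_r, c_c = int(risk["y"].sum()), int(ctl["y"].sum())
    l_r, l_c = float(risk["length"].sum()), float(ctl["length"].sum())
    base = dict(
        events_exposed=c_r,
        events_comparator=c_c,
        exposed_time=l_r / DAYS_PER_YEAR,
        comparator_time=l_c / DAYS_PER_YEAR,
    )
    n = c_r + c_c
    if n == 0 or l_r == 0 or l_c == 0:
        return make_record(estimable=False, **base)
    p0 = l_r / (l_r + l_c)
    p_one = float(stats.binom.sf(c_r - 1, n, p0))
    ci = stats.binomtest(c_r, n).proportion_ci(confidence_level=0.95, method="exact")

    def irr_of(p):  # map risk-window proportion to rate ratio
        if p >= 1.0:
            return np.inf
        return (p / (1 - p)) * (l_c / l_r)

    ci_lower, ci_upper = irr_of(ci.low), irr_of(ci.high)
    if c_r == 0 or c_c == 0:
        return make_record(
            p_one_sided=p_one, ci_lower=float(ci_lower), ci_upper=float(ci_upper),
            estimable=False, **base,
        )
    log_irr = float(np.log((c_r / l_r) / (c_c / l_c)))
    se = float(np.sqrt(1 / c_r + 1 / c_c))
    return make_record(
        log_estimate=log_irr,
        se=se,
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        p_one_sided=p_one,
        estimable=True,
        **base,
    )


def run_self_controlled(
    tables: EventTables,
    outcome_ids,
    config: SimulationConfig,
    variant: str,
    look_cutoff: int,
    rng=None,
) -> pd.DataFrame:
    """Estimate all outcomes for one SCCS/SCRI variant at one look."""
    from .estimates import records_frame

    ss = config.study_window[0]
    # intervals depend only on vaccination schedules: build once for persons
    # with any in-window event, per outcome below
    vacc_pids = set(tables.vaccinations.loc[tables.vaccinations["date"] <= look_cutoff, "person_id"])
    out = tables.outcomes
    out = out[(out["date"] >= ss) & (out["date"] <= look_cutoff)]
    case_pids = set(out["person_id"]) & vacc_pids
    intervals = build_intervals(
        tables.vaccinations, tables.observation_periods, config, variant, look_cutoff,
        person_ids=case_pids,
    )
    records = []
    for oid in outcome_ids:
        ev = out[out["outcome_id"] == oid][["person_id", "date"]]
        if variant.startswith("scri"):
            rec = fit_scri(intervals, ev, config, look_cutoff)
        else:
            rec = fit_sccs(
                intervals, ev, config, adjust=(variant == "sccs_age_season"),
                look_cutoff=look_cutoff, persons=tables.persons,
            )
        rec.update(
            design="sccs" if variant.startswith("sccs") else "scri",
            variant=variant,
            outcome_id=oid,
            true_effect_size=1.0,
        )
        records.append(rec)
    return records_frame(records)
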