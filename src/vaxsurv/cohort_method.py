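"""Concurrent comparative cohort design with propensity-score adjustment.

The vaccinated cohort is compared with a concurrent non-vaccinated
comparator cohort over the 1-28 day time-at-risk after the index date. Ten
variants cross the comparator index-date anchor with the adjustment:

* anchor ``visit``: comparator index dates are outpatient-visit dates
  (the comparator is, like the vaccinee, in contact with care that day);
* anchor ``random_day``: comparator index dates are uniform random days in
  the person's observed study time.

Adjustments: none (1:1 sampling), propensity-score 1:1 matching,
quintile stratification, ATT weighting, and per-month matching (matches
formed within each calendar month of index and frozen at later looks).
Propensity scores come from L1-regularised logistic regression over a
generic covariate set (demographics, prior-year visit counts, per-outcome
history indicators); the latent frailty and health-seeking scores are *not*
covariates, emulating confounders missing from real data. The outcome model
is a Cox proportional-hazards fit (Breslow ties) on time to first outcome
within the time-at-risk, stratified by matched set / PS stratum and weighted
for the weighting variant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from ._dates import age_years, month_index
from .estimates import make_record, records_frame, wald_fields
from .historical_comparator import age_band
from .synthetic_data import EventTables, SimulationConfig

__all__ = [
    "sample_comparator",
    "build_covariates",
    "fit_propensity",
    "match_on_ps",
    "stratify_on_ps",
    "att_weights",
    "estimate_hr",
    "run_cohort",
    "COHORT_VARIANTS",
]

# variant -> (anchor, adjustment, sampling_ratio)
COHORT_VARIANTS = {
    "unadj_visit": ("visit", "none", 1),
    "unadj_random": ("random_day", "none", 1),
    "ps_match_visit": ("visit", "match", 4),
    "ps_match_random": ("random_day", "match", 4),
    "ps_strat_visit": ("visit", "stratify", 4),
    "ps_strat_random": ("random_day", "stratify", 4),
    "ps_weight_visit": ("visit", "weight", 4),
    "ps_weight_random": ("random_day", "weight", 4),
    "ps_month_match_visit": ("visit", "per_month_match", 4),
    "ps_month_match_random": ("random_day", "per_month_match", 4),
}


def vaccinated_cohort(tables: EventTables, config: SimulationConfig, look_cutoff: int) -> pd.DataFrame:
    """Vaccination index dates up to the cutoff (one row per dose)."""
    v = tables.vaccinations
    v = v[v["date"] <= look_cutoff]
    return pd.DataFrame({"person_id": v["person_id"], "index_date": v["date"], "treated": 1})


def sample_comparator(
    tables: EventTables,
    config: SimulationConfig,
    anchor: str,
    n_target: int,
    look_cutoff: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample a non-vaccinated comparator cohort of up to ``n_target`` persons.

    A candidate is excluded if they have a vaccination on or before their
    candidate index date; index dates lie in the study period, before the
    cutoff, and inside the candidate's observation period. If fewer eligible
    candidates exist than requested, all are returned (the shortfall is the
    caller's to flag).
    """
    ss, se = config.study_window
    hi = min(se, look_cutoff)
    first_vacc = tables.vaccinations.groupby("person_id")["date"].min()

    if anchor == "visit":
        v = tables.visits
        v = v[(v["date"] >= ss) & (v["date"] <= hi)]
        fv = first_vacc.reindex(v["person_id"]).to_numpy()
        ok = ~(fv <= v["date"].to_numpy())  # NaN -> never vaccinated -> eligible
        pool = v[ok]
        if len(pool) == 0:
            return pd.DataFrame(columns=["person_id", "index_date", "treated"])
        pool = pool.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
        pool = pool.drop_duplicates("person_id").head(n_target)
        return pd.DataFrame(
            {"person_id": pool["person_id"].to_numpy(), "index_date": pool["date"].to_numpy(), "treated": 0}
        )

    if anchor != "random_day":
        raise ValueError(f"unknown anchor {anchor!r}")
    periods = tables.observation_periods
    lo = np.maximum(periods["start"].to_numpy(), ss)
    up = np.minimum(periods["end"].to_numpy(), hi)
    in_window = lo <= up
    cand = periods["person_id"].to_numpy()[in_window]
    lo, up = lo[in_window], up[in_window]
    dates = rng.integers(lo, up + 1) if len(cand) else np.array([], dtype=int)
    fv = first_vacc.reindex(cand).to_numpy()
    ok = ~(fv <= dates)
    cand, dates = cand[ok], dates[ok]
    if len(cand) > n_target:
        take = rng.choice(len(cand), n_target, replace=False)
        cand, dates = cand[take], dates[take]
    return pd.DataFrame({"person_id": cand, "index_date": dates, "treated": 0})


def build_covariates(
    cohort: pd.DataFrame,
    tables: EventTables,
    config: SimulationConfig,
    lookback_days: int = 365,
    include_latents: bool = False,
) -> pd.DataFrame:
    """Pre-index covariates: demographics, visit counts, per-outcome history.

    Binary indicators record whether each outcome occurred in the lookback
    window before (and excluding) the index date; visit counts are log1p of
    the lookback visit total. No post-index information enters. Setting
    ``include_latents`` adds the true frailty and health-seeking scores —
    useful to show PS adjustment works when all confounders are measured.
    """
    pmeta = tables.persons.set_index("person_id")
    pid = cohort["person_id"].to_numpy()
    idx = cohort["index_date"].to_numpy()
    X = pd.DataFrame(index=cohort.index)
    age = age_years(idx, pmeta.loc[pid, "birth_date"].to_numpy())
    X["age"] = age
    for b in np.unique(age_band(age)):
        X[f"age_band_{b}"] = (age_band(age) == b).astype(float)
    X["sex_F"] = (pmeta.loc[pid, "sex"].to_numpy() == "F").astype(float)
    for m in np.unique(month_index(idx, config.study_window[0])):
        X[f"index_month_{m}"] = (month_index(idx, config.study_window[0]) == m).astype(float)

    key = pd.DataFrame({"person_id": pid, "index_date": idx, "row": np.arange(len(pid))})
    visits = tables.visits.merge(key, on="person_id")
    visits = visits[
        (visits["date"] < visits["index_date"])
        & (visits["date"] >= visits["index_date"] - lookback_days)
    ]
    vcount = visits.groupby("row").size()
    X["log_visits"] = np.log1p(pd.Series(0.0, index=X.index).add(vcount, fill_value=0).to_numpy())

    hist = tables.outcomes.merge(key, on="person_id")
    hist = hist[
        (hist["date"] < hist["index_date"]) & (hist["date"] >= hist["index_date"] - lookback_days)
    ]
    for oid, g in hist.groupby("outcome_id"):
        col = np.zeros(len(X))
        col[g["row"].to_numpy()] = 1.0
        X[f"hist_{oid}"] = col

    if include_latents:
        X["frailty"] = pmeta.loc[pid, "frailty"].to_numpy()
        X["health_seeking"] = pmeta.loc[pid, "health_seeking"].to_numpy()
    return X


def fit_propensity(X: pd.DataFrame, treated: np.ndarray, seed: int = 0) -> np.ndarray:
    """Propensity scores from L1-penalised logistic regression (CV-chosen C)."""
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.preprocessing import StandardScaler

    treated = np.asarray(treated)
    if len(np.unique(treated)) < 2:
        raise ValueError("propensity model needs both treated and comparator subjects")
    Z = StandardScaler().fit_transform(X.to_numpy(dtype=float))
    model = LogisticRegressionCV(
        Cs=5, cv=3, penalty="l1", solver="liblinear", scoring="neg_log_loss",
        random_state=seed, max_iter=200,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z, treated)
        ps = model.predict_proba(Z)[:, 1]
    return np.clip(ps, 1e-6, 1 - 1e-6)


def match_on_ps(
    cohort: pd.DataFrame, ps: np.ndarray, caliper_sd: float = 0.2
) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbour matching on logit(PS) with a caliper.

    The caliper is ``caliper_sd`` standard deviations of the pooled
    logit-propensity distribution. Returns the matched subset with a
    ``match_id`` column.
    """
    logit = np.log(ps / (1 - ps))
    caliper = caliper_sd * np.std(logit)
    t_idx = np.flatnonzero(cohort["treated"].to_numpy() == 1)
    c_idx = np.flatnonzero(cohort["treated"].to_numpy() == 0)
    order_t = t_idx[np.argsort(logit[t_idx])]
    order_c = c_idx[np.argsort(logit[c_idx])]
    lc = logit[order_c]
    used = np.zeros(len(order_c), dtype=bool)
    pairs = []
    for t in order_t:
        j = np.searchsorted(lc, logit[t])
        best, best_d = -1, np.inf
        for k in (j - 1, j, j + 1):
            kk = k
            # walk outward past used controls
            while 0 <= kk < len(lc) and used[kk]:
                kk += 1 if k >= j else -1
            if 0 <= kk < len(lc):
                d = abs(lc[kk] - logit[t])
                if d < best_d:
                    best, best_d = kk, d
        if best >= 0 and best_d <= caliper:
            used[best] = True
            pairs.append((t, order_c[best]))
    rows, match_ids = [], []
    for mid, (t, c) in enumerate(pairs):
        rows += [t, c]
        match_ids += [mid, mid]
    matched = cohort.iloc[rows].copy()
    matched["match_id"] = match_ids
    matched["weight"] = 1.0
    return matched


def stratify_on_ps(cohort: pd.DataFrame, ps: np.ndarray, n_strata: int = 5) -> pd.DataFrame:
    """PS quintile stratification; empty/one-armed strata are dropped."""
    edges = np.quantile(ps, np.linspace(0, 1, n_strata + 1))
    stratum = np.clip(np.searchsorted(edges, ps, side="right") - 1, 0, n_strata - 1)
    out = cohort.copy()
    out["stratum"] = stratum
    out["weight"] = 1.0
    keep = out.groupby("stratum")["treated"].transform(lambda s: s.nunique() == 2)
    return out[keep]


def att_weights(cohort: pd.DataFrame, ps: np.ndarray, truncate_pct: float = 99.0) -> pd.DataFrame:
    """ATT weights: 1 for vaccinated, PS/(1-PS) for comparators, truncated."""
    w = np.where(cohort["treated"].to_numpy() == 1, 1.0, ps / (1 - ps))
    comp = cohort["treated"].to_numpy() == 0
    if comp.any():
        cap = np.percentile(w[comp], truncate_pct)
        w = np.where(comp, np.minimum(w, cap), w)
    out = cohort.copy()
    out["weight"] = w
    return out


def per_month_match(
    cohort: pd.DataFrame,
    ps: np.ndarray,
    config: SimulationConfig,
    previous: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """PS matching within each calendar month of index, frozen across looks.

    ``previous`` carries matches formed at earlier looks; only months not yet
    matched are processed, and their matches are preserved verbatim.
    """
    months = month_index(cohort["index_date"].to_numpy(), config.study_window[0])
    done_months: set[int] = set()
    pieces = []
    next_mid = 0
    if previous is not None and len(previous):
        pieces.append(previous)
        done_months = set(previous["match_month"].unique())
        next_mid = int(previous["match_id"].max()) + 1
    for m in sorted(set(months) - done_months):
        sub = cohort[months == m]
        if sub["treated"].nunique() < 2:
            continue
        matched = match_on_ps(sub, ps[months == m])
        if len(matched):
            matched = matched.copy()
            matched["match_id"] += next_mid
            matched["match_month"] = m
            next_mid = int(matched["match_id"].max()) + 1
            pieces.append(matched)
    if not pieces:
        out = cohort.iloc[:0].copy()
        out["match_id"] = []
        out["match_month"] = []
        out["weight"] = []
        return out
    return pd.concat(pieces, ignore_index=True)


def _follow_up(
    cohort: pd.DataFrame,
    tables: EventTables,
    outcome_id: str,
    config: SimulationConfig,
    look_cutoff: int,
) -> pd.DataFrame:
    """Time-to-first-outcome within time-at-risk, with censoring.

    Follow-up runs from index + tar_start to the earliest of index +
    tar_end, observation end, the look cutoff, and (for comparators) the
    person's first vaccination. Subjects with the outcome on or before index
    are excluded (first-occurrence outcomes make them immune afterwards).
    """
    per = tables.observation_periods.set_index("person_id")
    out = tables.outcomes[tables.outcomes["outcome_id"] == outcome_id].set_index("person_id")["date"]
    first_vacc = tables.vaccinations.groupby("person_id")["date"].min()

    pid = cohort["person_id"].to_numpy()
    idx = cohort["index_date"].to_numpy()
    treated = cohort["treated"].to_numpy()
    ev_date = out.reindex(pid).to_numpy(dtype=float)
    obs_end = per.loc[pid, "end"].to_numpy(dtype=float)
    fv = first_vacc.reindex(pid).to_numpy(dtype=float)

    start = idx + config.tar_start_day
    end = np.minimum(idx + config.tar_end_day, np.minimum(obs_end, look_cutoff))
    censor_vacc = np.where((treated == 0) & np.isfinite(fv), fv - 1, np.inf)
    end = np.minimum(end, censor_vacc)

    prevalent = ev_date <= idx
    event = (ev_date >= start) & (ev_date <= end)
    time = np.where(event, ev_date, end) - start + 1.0

    df = cohort.copy()
    df["time"] = time
    df["event"] = event.astype(int)
    keep = (~prevalent) & (time > 0)
    return df[keep]


def estimate_hr(population: pd.DataFrame, strata_col: str | None = None, weighted: bool = False) -> dict:
    """Cox proportional-hazards fit of treated vs comparator over time-at-risk.

    Breslow tie handling; stratified by ``strata_col`` when given; robust
    sandwich variance when ``weighted``. Zero events in either arm yields a
    non-estimable record.
    """
    ev_t = int(population.loc[population["treated"] == 1, "event"].sum())
    ev_c = int(population.loc[population["treated"] == 0, "event"].sum())
    base = dict(
        events_exposed=ev_t,
        events_comparator=ev_c,
        exposed_time=float(population.loc[population["treated"] == 1, "time"].sum() / 365.25),
        comparator_time=float(population.loc[population["treated"] == 0, "time"].sum() / 365.25),
    )
    if ev_t == 0 or ev_c == 0:
        return make_record(estimable=False, **base)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if weighted:
                # weighted partial likelihood with robust sandwich variance
                cph = CoxPHFitter()
                cph.fit(
                    population[["time", "event", "treated", "weight"]].copy(),
                    duration_col="time",
                    event_col="event",
                    weights_col="weight",
                    robust=True,
                )
                beta = float(cph.params_["treated"])
                se = float(cph.standard_errors_["treated"])
            else:
                import statsmodels.api as sm

                res = sm.PHReg(
                    population["time"],
                    population[["treated"]],
                    status=population["event"],
                    strata=population[strata_col] if strata_col else None,
                    ties="breslow",
                ).fit(disp=0)
                beta = float(res.params[0])
                se = float(res.bse[0])
    except Exception:
        return make_record(estimable=False, **base)
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 10:
        return make_record(estimable=False, **base)
    return make_record(**wald_fields(beta, se), **base)


def run_cohort(
    tables: EventTables,
    outcome_ids,
    config: SimulationConfig,
    variant: str,
    look_cutoff: int,
    rng: np.random.Generator | None = None,
    state: dict | None = None,
) -> pd.DataFrame:
    """Estimate all outcomes for one cohort variant at one look.

    ``state`` (a dict the caller carries across looks) preserves per-month
    matches for the per-month matching variants.
    """
    anchor, adjustment, ratio = COHORT_VARIANTS[variant]
    rng = rng or np.random.default_rng(config.seed)
    vacc = vaccinated_cohort(tables, config, look_cutoff)
    if len(vacc) == 0:
        return records_frame(
            [
                make_record(design="cohort", variant=variant, outcome_id=oid,
                            true_effect_size=1.0, estimable=False)
                for oid in outcome_ids
            ]
        )
    comp = sample_comparator(tables, config, anchor, ratio * len(vacc), look_cutoff, rng)
    cohort = pd.concat([vacc, comp], ignore_index=True)

    strata_col, weighted = None, False
    if adjustment != "none":
        X = build_covariates(cohort, tables, config)
        ps = fit_propensity(X, cohort["treated"].to_numpy(), seed=int(rng.integers(2**31)))
        if adjustment == "match":
            cohort = match_on_ps(cohort, ps)
            strata_col = "match_id"
        elif adjustment == "stratify":
            cohort = stratify_on_ps(cohort, ps)
            strata_col = "stratum"
        elif adjustment == "weight":
            cohort = att_weights(cohort, ps)
            weighted = True
        elif adjustment == "per_month_match":
            prev = (state or {}).get(variant)
            cohort = per_month_match(cohort, ps, config, previous=prev)
            if state is not None:
                state[variant] = cohort
            strata_col = "match_id"

    records = []
    for oid in outcome_ids:
        pop = _follow_up(cohort, tables, oid, config, look_cutoff)
        rec = estimate_hr(pop, strata_col=strata_col, weighted=weighted)
        rec.update(design="cohort", variant=variant, outcome_id=oid, true_effect_size=1.0)
        records.append(rec)
    return records_frame(records)
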