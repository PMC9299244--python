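"""Historical comparator design: observed vs expected time-at-risk counts.

The expected count is derived from the incidence rate in a historic period
preceding the surveillance study; the observed count is the number of
first-occurrence outcomes during the 1-28 day time-at-risk after each
vaccination. Eight variants cross three switches:

* background-rate anchor: the whole historic period, or only the
  time-at-risk after one random outpatient visit per person (emulating the
  care-seeking context of a vaccination visit);
* adjustment: none, or age-band x sex stratified rates recombined over the
  vaccinees' strata;
* instability filter: drop outcomes whose overall incidence changed by more
  than 50% between the historic period and the surveillance period so far.

The incidence rate ratio is observed/expected with an exact Poisson
(Garwood) interval and a one-sided Poisson tail p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._dates import DAYS_PER_YEAR, age_years
from .estimates import make_record, records_frame
from .synthetic_data import EventTables, SimulationConfig

__all__ = [
    "historic_rate",
    "expected_count",
    "estimate_irr",
    "instability_filter",
    "run_historical",
    "HISTORICAL_VARIANTS",
]

AGE_BAND_YEARS = 5


def age_band(age: np.ndarray) -> np.ndarray:
    return (np.asarray(age, dtype=float) // AGE_BAND_YEARS).astype(int)


def _overlap_days(start, end, lo: int, hi: int) -> np.ndarray:
    """Days of [start, end] inside [lo, hi], inclusive bounds, floored at 0."""
    return np.maximum(np.minimum(end, hi) - np.maximum(start, lo) + 1, 0)


def historic_rate(
    tables: EventTables,
    outcome_ids,
    window: tuple[int, int],
    anchor: str = "whole_period",
    strata: str | None = None,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Incidence rates (per 1,000 person-years) in the historic window.

    Returns one row per outcome (and per age-band x sex stratum when
    ``strata == "age_sex"``) with events, person_years, rate and a
    ``defined`` flag (False where the stratum has zero person-time).

    With ``anchor == "post_visit"`` one outpatient visit in the window is
    sampled uniformly per person (seeded via ``rng``) and only the
    time-at-risk-sized window after it contributes events and person-time.
    """
    lo, hi = window
    persons = tables.persons
    periods = tables.observation_periods.set_index("person_id")
    tar_start = config.tar_start_day if config else 1
    tar_end = config.tar_end_day if config else 28

    if anchor == "whole_period":
        start = np.maximum(periods["start"].to_numpy(), lo)
        end = np.minimum(periods["end"].to_numpy(), hi)
        days = np.maximum(end - start + 1, 0)
        pid = periods.index.to_numpy()
        win_lo = np.full(len(pid), lo)
        win_hi = np.full(len(pid), hi)
    elif anchor == "post_visit":
        if rng is None:
            rng = np.random.default_rng(0)
        v = tables.visits
        v = v[(v["date"] >= lo) & (v["date"] <= hi)]
        # one uniformly random in-window visit per person
        v = v.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
        v = v.drop_duplicates("person_id")
        pid = v["person_id"].to_numpy()
        vdate = v["date"].to_numpy()
        obs_end = periods.loc[pid, "end"].to_numpy()
        win_lo = vdate + tar_start
        win_hi = np.minimum(np.minimum(vdate + tar_end, obs_end), hi)
        days = np.maximum(win_hi - win_lo + 1, 0)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    info = pd.DataFrame({"person_id": pid, "days": days, "win_lo": win_lo, "win_hi": win_hi})
    pmeta = persons.set_index("person_id")
    info["sex"] = pmeta.loc[info["person_id"], "sex"].to_numpy()
    # stratification age is measured at a common reference day (study start) on
    # both the historic and the vaccinee side, so band membership cannot drift
    # between the two periods
    ref_day = config.study_window[0] if config else hi
    info["age_band"] = age_band(
        age_years(ref_day, pmeta.loc[info["person_id"], "birth_date"].to_numpy())
    )
    info = info[info["days"] > 0]

    # events: first occurrences falling inside each person's counting window
    out = tables.outcomes[tables.outcomes["outcome_id"].isin(list(outcome_ids))]
    merged = out.merge(info, on="person_id", how="inner")
    merged = merged[(merged["date"] >= merged["win_lo"]) & (merged["date"] <= merged["win_hi"])]

    group_cols = ["age_band", "sex"] if strata == "age_sex" else []
    if group_cols:
        pt = info.groupby(group_cols)["days"].sum()
        ev = merged.groupby(["outcome_id"] + group_cols).size()
        rows = []
        for oid in outcome_ids:
            for stratum, days_s in pt.items():
                e = int(ev.get((oid, *stratum), 0))
                py = days_s / DAYS_PER_YEAR
                rows.append(
                    {
                        "outcome_id": oid,
                        "age_band": stratum[0],
                        "sex": stratum[1],
                        "events": e,
                        "person_years": py,
                        "rate": 1000.0 * e / py if py > 0 else np.nan,
                        "defined": py > 0,
                    }
                )
        return pd.DataFrame(rows)

    total_days = info["days"].sum()
    py = total_days / DAYS_PER_YEAR
    ev = merged.groupby("outcome_id").size()
    rows = [
        {
            "outcome_id": oid,
            "events": int(ev.get(oid, 0)),
            "person_years": py,
            "rate": 1000.0 * int(ev.get(oid, 0)) / py if py > 0 else np.nan,
            "defined": py > 0,
        }
        for oid in outcome_ids
    ]
    return pd.DataFrame(rows)


def tar_person_time(
    tables: EventTables, config: SimulationConfig, look_cutoff: int
) -> pd.DataFrame:
    """Per-vaccination time-at-risk days, truncated at observation end and cutoff."""
    vacc = tables.vaccinations
    vacc = vacc[vacc["date"] <= look_cutoff]
    periods = tables.observation_periods.set_index("person_id")
    obs_end = periods.loc[vacc["person_id"], "end"].to_numpy()
    start = vacc["date"].to_numpy() + config.tar_start_day
    end = np.minimum.reduce(
        [vacc["date"].to_numpy() + config.tar_end_day, obs_end, np.full(len(vacc), look_cutoff)]
    )
    days = np.maximum(end - start + 1, 0)
    out = vacc[["person_id", "date"]].rename(columns={"date": "vacc_date"})
    out["tar_days"] = days
    out["tar_start"] = start
    out["tar_end"] = end
    return out


def expected_count(
    rates: pd.DataFrame,
    tables: EventTables,
    config: SimulationConfig,
    look_cutoff: int,
    adjusted: bool = False,
) -> pd.DataFrame:
    """Expected time-at-risk counts per outcome: sum of rate x TaR person-time.

    For the adjusted variant the vaccinees' time-at-risk is split by
    age band (at vaccination) and sex and combined with the stratified
    historic rates; a vaccinee stratum with no defined historic rate raises.
    """
    tar = tar_person_time(tables, config, look_cutoff)
    outcome_ids = rates["outcome_id"].unique()
    if not adjusted:
        py = tar["tar_days"].sum() / DAYS_PER_YEAR
        res = rates[["outcome_id", "rate"]].copy()
        res["expected"] = res["rate"] / 1000.0 * py
        res["tar_person_years"] = py
        return res[["outcome_id", "expected", "tar_person_years"]]

    pmeta = tables.persons.set_index("person_id")
    tar = tar.copy()
    tar["sex"] = pmeta.loc[tar["person_id"], "sex"].to_numpy()
    tar["age_band"] = age_band(
        age_years(config.study_window[0], pmeta.loc[tar["person_id"], "birth_date"].to_numpy())
    )
    strata_py = tar.groupby(["age_band", "sex"])["tar_days"].sum() / DAYS_PER_YEAR
    total_py = float(strata_py.sum())

    rate_map = rates.set_index(["outcome_id", "age_band", "sex"])
    rows = []
    for oid in outcome_ids:
        expected = 0.0
        for (band, sex), py in strata_py.items():
            if py <= 0:
                continue
            try:
                r = rate_map.loc[(oid, band, sex)]
            except KeyError:
                raise ValueError(
                    f"no historic rate for stratum (age_band={band}, sex={sex}) "
                    f"of outcome {oid}"
                ) from None
            if not bool(r["defined"]):
                raise ValueError(
                    f"historic rate undefined for stratum (age_band={band}, sex={sex}) "
                    f"of outcome {oid}"
                )
            expected += float(r["rate"]) / 1000.0 * py
        rows.append({"outcome_id": oid, "expected": expected, "tar_person_years": total_py})
    return pd.DataFrame(rows)


def estimate_irr(c: int, u: float) -> dict:
    """Incidence rate ratio c/u with exact Poisson (Garwood) 95% CI.

    The log SE is recovered from the CI width; the one-sided p-value is the
    Poisson upper tail P(X >= c | u). A zero observed count is flagged
    non-estimable (log estimate undefined), with CI [0, upper].
    """
    if u <= 0:
        raise ValueError("expected count u must be positive")
    c = int(c)
    ci_lower = stats.chi2.ppf(0.025, 2 * c) / 2 / u if c > 0 else 0.0
    ci_upper = stats.chi2.ppf(0.975, 2 * (c + 1)) / 2 / u
    p = float(stats.poisson.sf(c - 1, u))
    if c == 0:
        return make_record(
            ci_lower=0.0, ci_upper=float(ci_upper), p_one_sided=p, expected=u,
            events_exposed=0, estimable=False,
        )
    log_est = float(np.log(c / u))
    se = float((np.log(ci_upper) - np.log(max(ci_lower, 1e-12))) / (2 * 1.96))
    return make_record(
        log_estimate=log_est,
        se=se,
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        p_one_sided=p,
        events_exposed=c,
        expected=float(u),
        estimable=True,
    )


def instability_filter(rate_historic: float, rate_now: float, threshold: float = 0.5) -> bool:
    """True = keep, False = drop: relative rate change above the threshold drops.

    A historic rate of zero with any current events drops the outcome; both
    zero keeps it.
    """
    if rate_historic == 0:
        return rate_now == 0
    return abs(rate_now - rate_historic) / rate_historic <= threshold


# (anchor, adjusted, filtered)
HISTORICAL_VARIANTS = {
    "unadj": ("whole_period", False, False),
    "age_sex": ("whole_period", True, False),
    "unadj_post_visit": ("post_visit", False, False),
    "age_sex_post_visit": ("post_visit", True, False),
    "unadj_filtered": ("whole_period", False, True),
    "age_sex_filtered": ("whole_period", True, True),
    "unadj_post_visit_filtered": ("post_visit", False, True),
    "age_sex_post_visit_filtered": ("post_visit", True, True),
}


def run_historical(
    tables: EventTables,
    outcome_ids,
    config: SimulationConfig,
    variant: str,
    look_cutoff: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Estimate all outcomes for one historical-comparator variant at one look."""
    anchor, adjusted, filtered = HISTORICAL_VARIANTS[variant]
    rng = rng or np.random.default_rng(config.seed)
    strata = "age_sex" if adjusted else None
    rates = historic_rate(
        tables, outcome_ids, config.historic_window, anchor=anchor, strata=strata,
        config=config, rng=rng,
    )
    expected = expected_count(
        rates, tables, config, look_cutoff, adjusted=adjusted
    ).set_index("outcome_id")

    # observed time-at-risk counts
    tar = tar_person_time(tables, config, look_cutoff)
    out = tables.outcomes[tables.outcomes["outcome_id"].isin(list(outcome_ids))]
    merged = out.merge(tar, on="person_id", how="inner")
    in_tar = merged[(merged["date"] >= merged["tar_start"]) & (merged["date"] <= merged["tar_end"])]
    observed = in_tar.groupby("outcome_id").size()

    if filtered:
        overall_hist = (
            rates.groupby("outcome_id")
            .apply(
                lambda g: 1000.0 * g["events"].sum() / g["person_years"].sum()
                if g["person_years"].sum() > 0
                else np.nan,
                include_groups=False,
            )
            if strata
            else rates.set_index("outcome_id")["rate"]
        )
        now = _surveillance_rate(tables, outcome_ids, config, look_cutoff)

    records = []
    for oid in outcome_ids:
        u = float(expected.loc[oid, "expected"])
        c = int(observed.get(oid, 0))
        if filtered and not instability_filter(float(overall_hist.loc[oid]), float(now.loc[oid])):
            rec = make_record(estimable=False, events_exposed=c, expected=u)
        elif u <= 0:
            rec = make_record(estimable=False, events_exposed=c, expected=u)
        else:
            rec = estimate_irr(c, u)
        rec.update(
            design="historical_comparator",
            variant=variant,
            outcome_id=oid,
            true_effect_size=1.0,
            exposed_time=float(expected.loc[oid, "tar_person_years"]),
        )
        records.append(rec)
    return records_frame(records)


def _surveillance_rate(tables, outcome_ids, config, look_cutoff) -> pd.Series:
    """Overall incidence per 1,000 py from study start through the cutoff."""
    lo = config.study_window[0]
    periods = tables.observation_periods
    days = _overlap_days(periods["start"].to_numpy(), periods["end"].to_numpy(), lo, look_cutoff)
    py = days.sum() / DAYS_PER_YEAR
    out = tables.outcomes[tables.outcomes["outcome_id"].isin(list(outcome_ids))]
    ev = out[(out["date"] >= lo) & (out["date"] <= look_cutoff)].groupby("outcome_id").size()
    return pd.Series(
        {oid: 1000.0 * int(ev.get(oid, 0)) / py if py > 0 else np.nan for oid in outcome_ids}
    )
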