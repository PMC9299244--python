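"""Case-control design: exposure odds among cases versus controls.

Cases are persons whose first outcome occurrence falls in the study period;
controls are outcome-free persons. Exposure is a vaccination in the 28-day
window before the index date (mirroring the 1-28 day time-at-risk). Two
variants:

* ``matched``: up to four controls per case sharing the case's 5-year age
  band and sex, with the case's outcome date as their index; conditional
  logistic regression over matched sets.
* ``random``: controls drawn from all eligible persons with index dates
  resampled from the empirical distribution of case outcome dates;
  unconditional logistic regression with age-band and sex terms.

Both cases and controls must be observed for the 365 days before index and
outcome-free through it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._dates import age_years
from .estimates import make_record, records_frame, wald_fields
from .historical_comparator import age_band
from .synthetic_data import EventTables, SimulationConfig

__all__ = [
    "select_cases",
    "sample_controls",
    "assess_exposure",
    "estimate_or",
    "run_case_control",
    "CASE_CONTROL_VARIANTS",
]

CASE_CONTROL_VARIANTS = ["matched", "random"]
MAX_CONTROLS_PER_CASE = 4
PRIOR_OBSERVATION_DAYS = 365


def select_cases(
    tables: EventTables, outcome_id: str, config: SimulationConfig, look_cutoff: int
) -> pd.DataFrame:
    """First in-study occurrences up to the cutoff, with 365 d prior observation."""
    ss, _ = config.study_window
    out = tables.outcomes
    cases = out[
        (out["outcome_id"] == outcome_id) & (out["date"] >= ss) & (out["date"] <= look_cutoff)
    ][["person_id", "date"]].rename(columns={"date": "index_date"})
    per = tables.observation_periods.set_index("person_id")
    obs_start = per.loc[cases["person_id"], "start"].to_numpy()
    obs_end = per.loc[cases["person_id"], "end"].to_numpy()
    ok = (cases["index_date"].to_numpy() - obs_start >= PRIOR_OBSERVATION_DAYS) & (
        cases["index_date"].to_numpy() <= obs_end
    )
    return cases[ok].reset_index(drop=True)


def _eligible_controls(
    tables: EventTables, outcome_id: str, index_dates: np.ndarray, person_ids: np.ndarray
) -> np.ndarray:
    """Mask: observed 365 d before index, observed at index, outcome-free through it."""
    per = tables.observation_periods.set_index("person_id")
    first = (
        tables.outcomes[tables.outcomes["outcome_id"] == outcome_id]
        .set_index("person_id")["date"]
        .reindex(person_ids)
        .to_numpy(dtype=float)
    )
    obs_start = per.loc[person_ids, "start"].to_numpy()
    obs_end = per.loc[person_ids, "end"].to_numpy()
    return (
        (index_dates - obs_start >= PRIOR_OBSERVATION_DAYS)
        & (index_dates <= obs_end)
        & ~(first <= index_dates)
    )


def sample_controls(
    cases: pd.DataFrame,
    tables: EventTables,
    outcome_id: str,
    variant: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Case-control sets: columns person_id, index_date, is_case, set_id.

    Matched controls are drawn without replacement within a set but may be
    reused across sets; a case with no eligible control keeps an empty set
    (it then drops out of the conditional likelihood).
    """
    pmeta = tables.persons.set_index("person_id")
    all_pids = pmeta.index.to_numpy()
    rows = []
    if variant == "matched":
        bands = age_band(age_years(cases["index_date"].to_numpy(),
                                   pmeta.loc[cases["person_id"], "birth_date"].to_numpy()))
        sexes = pmeta.loc[cases["person_id"], "sex"].to_numpy()
        all_sex = pmeta["sex"].to_numpy()
        all_birth = pmeta["birth_date"].to_numpy()
        for set_id, (case, band, sex) in enumerate(zip(cases.itertuples(), bands, sexes)):
            idx = case.index_date
            cand_mask = (all_sex == sex) & (age_band(age_years(idx, all_birth)) == band)
            cand = all_pids[cand_mask]
            cand = cand[cand != case.person_id]
            ok = _eligible_controls(tables, outcome_id, np.full(len(cand), idx), cand)
            cand = cand[ok]
            chosen = rng.choice(cand, min(MAX_CONTROLS_PER_CASE, len(cand)), replace=False)
            rows.append((case.person_id, idx, 1, set_id))
            rows += [(c, idx, 0, set_id) for c in chosen]
    elif variant == "random":
        case_dates = cases["index_date"].to_numpy()
        for set_id, case in enumerate(cases.itertuples()):
            rows.append((case.person_id, case.index_date, 1, set_id))
        n_controls = MAX_CONTROLS_PER_CASE * len(cases)
        pid = rng.choice(all_pids, 3 * n_controls, replace=True)
        idx = rng.choice(case_dates, 3 * n_controls, replace=True)
        ok = _eligible_controls(tables, outcome_id, idx, pid)
        pid, idx = pid[ok][:n_controls], idx[ok][:n_controls]
        rows += [(p, i, 0, -1) for p, i in zip(pid, idx)]
    else:
        raise ValueError(f"unknown case-control variant {variant!r}")
    return pd.DataFrame(rows, columns=["person_id", "index_date", "is_case", "set_id"])


def assess_exposure(
    sets: pd.DataFrame, vaccinations: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Exposure flag: any vaccination in [index - tar_end, index - tar_start].

    Doses count as separate exposures; either dose in the window qualifies.
    A vaccination on the index date itself is unexposed (day 0 lies outside
    the 1-28 day window).
    """
    out = sets.copy()
    merged = sets.reset_index().merge(vaccinations, on="person_id", how="inner")
    in_window = (
        merged["date"] >= merged["index_date"] - config.tar_end_day
    ) & (merged["date"] <= merged["index_date"] - config.tar_start_day)
    exposed_rows = merged.loc[in_window, "index"].unique()
    out["exposed"] = 0
    out.loc[exposed_rows, "exposed"] = 1
    return out


def estimate_or(
    sets: pd.DataFrame, tables: EventTables, variant: str, config: SimulationConfig
) -> dict:
    """Odds ratio of exposure for cases versus controls.

    Matched: conditional logistic over sets (discordant sets informative).
    Random: unconditional logistic adjusted for age band and sex. Monotone
    (separated) likelihoods and no exposure variation yield non-estimable
    records.
    """
    n_case_exp = int(sets.loc[sets["is_case"] == 1, "exposed"].sum())
    n_ctl_exp = int(sets.loc[sets["is_case"] == 0, "exposed"].sum())
    base = dict(
        events_exposed=n_case_exp,
        events_comparator=n_ctl_exp,
    )
    if sets["exposed"].nunique() < 2:
        return make_record(estimable=False, **base)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if variant == "matched":
                from statsmodels.discrete.conditional_models import ConditionalLogit

                informative = sets.groupby("set_id").filter(
                    lambda g: g["exposed"].nunique() == 2 and g["is_case"].nunique() == 2
                )
                if len(informative) == 0:
                    return make_record(estimable=False, **base)
                model = ConditionalLogit(
                    informative["is_case"].to_numpy(dtype=float),
                    informative[["exposed"]].to_numpy(dtype=float),
                    groups=informative["set_id"].to_numpy(),
                )
                res = model.fit(disp=0, method="newton", tol=1e-10, maxiter=200)
            else:
                import statsmodels.api as sm

                pmeta = tables.persons.set_index("person_id")
                age = age_years(sets["index_date"].to_numpy(),
                                pmeta.loc[sets["person_id"], "birth_date"].to_numpy())
                X = pd.DataFrame({"exposed": sets["exposed"].to_numpy(dtype=float)})
                bands = age_band(age)
                for b in np.unique(bands)[1:]:
                    X[f"age_band_{b}"] = (bands == b).astype(float)
                X["sex_F"] = (pmeta.loc[sets["person_id"], "sex"].to_numpy() == "F").astype(float)
                X = sm.add_constant(X)
                res = sm.Logit(sets["is_case"].to_numpy(dtype=float), X).fit(disp=0, maxiter=100)
        except Exception:
            return make_record(estimable=False, **base)

    beta = float(res.params.iloc[0] if hasattr(res.params, "iloc") else res.params[0])
    name = "exposed"
    if hasattr(res, "bse") and hasattr(res.bse, "loc") and name in getattr(res.params, "index", []):
        beta = float(res.params.loc[name])
        se = float(res.bse.loc[name])
    else:
        se = float(res.bse[0] if not hasattr(res.bse, "iloc") else res.bse.iloc[0])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 10 or se > 50:
        return make_record(estimable=False, **base)
    return make_record(**wald_fields(beta, se), **base)


def run_case_control(
    tables: EventTables,
    outcome_ids,
    config: SimulationConfig,
    variant: str,
    look_cutoff: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Estimate all outcomes for one case-control variant at one look."""
    rng = rng or np.random.default_rng(config.seed)
    records = []
    for oid in outcome_ids:
        cases = select_cases(tables, oid, config, look_cutoff)
        if len(cases) == 0:
            rec = make_record(estimable=False)
        else:
            sets = sample_controls(cases, tables, oid, variant, config, rng)
            sets = assess_exposure(sets, tables.vaccinations, config)
            rec = estimate_or(sets, tables, variant, config)
        rec.update(
            design="case_control", variant=variant, outcome_id=oid, true_effect_size=1.0
        )
        records.append(rec)
    return records_frame(records)
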