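"""Orchestration of the full evaluation grid and performance metrics.

``run_grid`` executes every requested design variant on every outcome at
every monthly look of the study period, always on the data accumulated up
to that look. For each estimable negative-control estimate it imputes
positive controls at effect sizes 1.5, 2 and 4 (shifting the log estimate,
keeping the standard error), attaches MaxSPRT log-likelihood ratios and
per-(variant, outcome) critical values, and calibrates p-values and LLRs
leave-one-out against the negative-control systematic-error fit of the same
(variant, look).

Performance metrics follow: type 1 error (fraction of negative controls
rejected), type 2 error per true effect size (fraction of positives not
rejected), and months to 50% sensitivity (earliest look at which half the
positives of a size have signalled; signals persist once declared).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import impute_positive, loo_calibrate
from .case_control import CASE_CONTROL_VARIANTS, run_case_control
from .cohort_method import COHORT_VARIANTS, run_cohort
from .estimates import make_record, records_frame
from .historical_comparator import HISTORICAL_VARIANTS, run_historical
from .self_controlled import SELF_CONTROLLED_VARIANTS, run_self_controlled
from .sequential_testing import (
    LookSchedule,
    binomial_llr,
    critical_value,
    normal_llr,
    poisson_llr,
)
from .synthetic_data import EventTables, OutcomeDefinition, SimulationConfig

logger = logging.getLogger("vaxsurv")

__all__ = [
    "all_variants",
    "run_grid",
    "type1_error",
    "type2_error",
    "time_to_sensitivity",
    "summarize",
    "PerformanceResult",
]

IMPUTE_FACTORS = (1.5, 2.0, 4.0)
ALPHA = 0.05


def all_variants() -> list[tuple[str, str]]:
    """The full grid of 25 (design, variant) pairs."""
    grid = [("case_control", v) for v in CASE_CONTROL_VARIANTS]
    grid += [("cohort", v) for v in COHORT_VARIANTS]
    grid += [("historical_comparator", v) for v in HISTORICAL_VARIANTS]
    grid += [("self_controlled", v) for v in SELF_CONTROLLED_VARIANTS]
    return grid


_RUNNERS = {
    "case_control": run_case_control,
    "cohort": run_cohort,
    "historical_comparator": run_historical,
    "self_controlled": run_self_controlled,
}


def _run_one(design, tables, outcome_ids, config, variant, cutoff, rng, state):
    if design == "cohort":
        return run_cohort(tables, outcome_ids, config, variant, cutoff, rng, state=state)
    return _RUNNERS[design](tables, outcome_ids, config, variant, cutoff, rng)


def run_grid(
    tables: EventTables,
    outcome_definitions: list[OutcomeDefinition],
    config: SimulationConfig,
    variants: list[tuple[str, str]] | None = None,
    looks: np.ndarray | None = None,
    impute_factors: tuple[float, ...] = IMPUTE_FACTORS,
    calibrate: bool = True,
    cv_mc_reps: int = 20_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """The full estimates table: one row per variant x outcome x look (+ imputed).

    Any stage failure is recorded as a non-estimable row, never aborting the
    grid. Fully seeded: the same (tables, config, seed) reproduce the table.
    """
    variants = variants if variants is not None else all_variants()
    looks = np.asarray(looks if looks is not None else config.study_month_ends)
    seed = config.seed if seed is None else seed
    truth = {od.outcome_id: od.true_effect_size for od in outcome_definitions}
    outcome_ids = [od.outcome_id for od in outcome_definitions]

    frames = []
    state: dict = {}
    for design, variant in variants:
        vseed = zlib.crc32(f"{seed}:{design}:{variant}".encode()) % (2**31)
        for look_no, cutoff in enumerate(looks, start=1):
            rng = np.random.default_rng(vseed + look_no)
            try:
                df = _run_one(design, tables, outcome_ids, config, variant, int(cutoff), rng, state)
            except Exception as exc:  # record the failure, keep the grid going
                logger.warning("%s/%s look %d failed: %s", design, variant, look_no, exc)
                df = records_frame(
                    [
                        make_record(design=design, variant=variant, outcome_id=oid,
                                    true_effect_size=1.0, estimable=False)
                        for oid in outcome_ids
                    ]
                )
            df["design"] = design
            df["look_month"] = look_no
            df["true_effect_size"] = df["outcome_id"].map(truth)
            df["parent_outcome"] = df["outcome_id"]
            frames.append(df)

            # impute positives from this look's negative estimates
            negatives = df[(df["true_effect_size"] == 1.0) & df["estimable"]]
            imputed = []
            for k in impute_factors:
                for _, rec in negatives.iterrows():
                    new = impute_positive(rec, k)
                    new["outcome_id"] = f"{rec['outcome_id']}_x{k:g}"
                    new["parent_outcome"] = rec["outcome_id"]
                    imputed.append(new)
            if imputed:
                frames.append(pd.DataFrame(imputed))

    est = pd.concat(frames, ignore_index=True)
    est = _attach_llr_and_cv(est, cv_mc_reps, seed)
    if calibrate:
        est = _calibrate_grid(est)
    return est


def _attach_llr_and_cv(est: pd.DataFrame, mc_reps: int, seed: int) -> pd.DataFrame:
    """Per-record LLRs and per-(variant, outcome) MaxSPRT critical values.

    Historical-comparator records use the Poisson model on observed vs
    expected counts; self-controlled records the binomial model on the
    risk/control event split; cohort and case-control records (summarised by
    estimate and SE) the normal-approximation LLR with a boundary simulated
    from the Brownian score process at the observed information schedule.
    """
    est = est.copy()
    llr = np.zeros(len(est))
    design = est["design"].to_numpy()
    with np.errstate(invalid="ignore"):
        hist = design == "historical_comparator"
        c = est["events_exposed"].to_numpy(dtype=float)
        u = est["expected"].to_numpy(dtype=float)
        ok = hist & (u > 0) & np.isfinite(c)
        llr[ok] = poisson_llr(c[ok], u[ok])

        sc = np.isin(design, ["self_controlled"]) | est["variant"].isin(
            SELF_CONTROLLED_VARIANTS
        ).to_numpy()
        n = c + est["events_comparator"].to_numpy(dtype=float)
        z = est["comparator_time"].to_numpy(dtype=float) / est["exposed_time"].to_numpy(dtype=float)
        ok = sc & np.isfinite(n) & (n > 0) & np.isfinite(z) & (z > 0)
        llr[ok] = binomial_llr(c[ok], n[ok], z[ok])

        other = ~hist & ~sc
        th = est["log_estimate"].to_numpy(dtype=float)
        se = est["se"].to_numpy(dtype=float)
        ok = other & np.isfinite(th) & np.isfinite(se) & (se > 0)
        llr[ok] = normal_llr(th[ok], se[ok])
    est["llr"] = llr

    # shift imputed positives' binomial/poisson evidence is already encoded in
    # their shifted estimates; their LLR uses the same counts as the parent for
    # count models, so recompute normal-approximation LLR for imputed rows
    imputed = est["outcome_id"] != est["parent_outcome"]
    th = est["log_estimate"].to_numpy(dtype=float)
    se = est["se"].to_numpy(dtype=float)
    ok = imputed.to_numpy() & np.isfinite(th) & np.isfinite(se) & (se > 0)
    est.loc[ok, "llr"] = normal_llr(th[ok], se[ok])

    cvs = np.full(len(est), np.nan)
    for (design_v, variant, parent), g in est.groupby(["design", "variant", "parent_outcome"]):
        g = g.sort_values("look_month")
        base = g[g["outcome_id"] == g["parent_outcome"]]
        try:
            if design_v == "historical_comparator":
                expct = base.set_index("look_month")["expected"].astype(float)
                sched_vals = _ffill_cumulative(expct, g["look_month"].max())
                schedule = LookSchedule("poisson", sched_vals)
            elif design_v == "self_controlled":
                n = (base["events_exposed"] + base["events_comparator"]).astype(float)
                zr = (base["comparator_time"] / base["exposed_time"]).astype(float)
                n.index = base["look_month"]
                sched_vals = _ffill_cumulative(n, g["look_month"].max())
                z_last = zr.dropna().iloc[-1] if zr.notna().any() else 1.0
                schedule = LookSchedule("binomial", sched_vals, z=np.full(len(sched_vals), z_last))
            else:
                info = 1.0 / base["se"].astype(float) ** 2
                info.index = base["look_month"]
                sched_vals = _ffill_cumulative(info, g["look_month"].max())
                schedule = LookSchedule("normal", sched_vals)
            cv_seed = zlib.crc32(f"{seed}:{design_v}:{variant}:{parent}:cv".encode()) % (2**31)
            cv = critical_value(schedule, ALPHA, mc_reps=mc_reps, seed=cv_seed).value
        except (ValueError, IndexError):
            cv = np.nan
        cvs[g.index] = cv
    est["cv"] = cvs
    return est


def _ffill_cumulative(series: pd.Series, n_looks: int) -> np.ndarray:
    """Per-look schedule values: forward-filled, forced non-decreasing."""
    vals = series.reindex(range(1, int(n_looks) + 1)).ffill().fillna(0.0).to_numpy(dtype=float)
    return np.maximum.accumulate(np.where(np.isfinite(vals), vals, 0.0))


def _calibrate_grid(est: pd.DataFrame) -> pd.DataFrame:
    out = []
    for (design, variant, look), g in est.groupby(["design", "variant", "look_month"]):
        try:
            out.append(loo_calibrate(g, parent_col="parent_outcome"))
        except ValueError:
            g = g.copy()
            g["p_calibrated"] = np.nan
            g["llr_calibrated"] = np.nan
            out.append(g)
    return pd.concat(out).sort_index()


# ---------------------------------------------------------------------------
# performance metrics


@dataclass(frozen=True)
class PerformanceResult:
    design: str
    variant: str
    type1: float
    type1_calibrated: float
    type2: dict
    type2_calibrated: dict
    months_to_50pct: dict


def _rejected(records: pd.DataFrame, use_calibrated: bool, sequential: bool) -> pd.Series:
    if sequential:
        col = "llr_calibrated" if use_calibrated else "llr"
        return records[col] > records["cv"]
    col = "p_calibrated" if use_calibrated else "p_one_sided"
    return records[col] < ALPHA


def type1_error(
    records: pd.DataFrame, use_calibrated: bool = False, sequential: bool = False
) -> float:
    """Fraction of estimable negative-control records rejected."""
    neg = records[(records["true_effect_size"] == 1.0) & records["estimable"]]
    if len(neg) == 0:
        return np.nan
    return float(_rejected(neg, use_calibrated, sequential).mean())


def type2_error(
    records: pd.DataFrame,
    true_effect_size: float,
    use_calibrated: bool = False,
    sequential: bool = False,
) -> float:
    """Fraction of estimable positives of one true size NOT rejected."""
    pos = records[(records["true_effect_size"] == true_effect_size) & records["estimable"]]
    if len(pos) == 0:
        return np.nan
    return float((~_rejected(pos, use_calibrated, sequential)).mean())


def time_to_sensitivity(
    records: pd.DataFrame, target: float = 0.5, use_calibrated: bool = True
) -> dict:
    """Months until >= ``target`` of each size's positives have signalled.

    A positive control signals at the first look where its (calibrated) LLR
    exceeds the critical value; signals persist at later looks. Returns
    {true_effect_size: month or None}.
    """
    col = "llr_calibrated" if use_calibrated else "llr"
    out = {}
    pos = records[records["true_effect_size"] > 1.0]
    for size, g in pos.groupby("true_effect_size"):
        outcomes = g["outcome_id"].unique()
        looks = np.sort(records["look_month"].unique())
        signal_month = {}
        for oid, go in g.groupby("outcome_id"):
            go = go.sort_values("look_month")
            hit = go[(go[col] > go["cv"]) & go["estimable"]]
            if len(hit):
                signal_month[oid] = int(hit["look_month"].iloc[0])
        month = None
        for m in looks:
            frac = np.mean([signal_month.get(o, np.inf) <= m for o in outcomes])
            if frac >= target:
                month = int(m)
                break
        out[float(size)] = month
    return out


def summarize(records: pd.DataFrame) -> list[PerformanceResult]:
    """One PerformanceResult per executed (design, variant)."""
    results = []
    for (design, variant), g in records.groupby(["design", "variant"]):
        sizes = sorted(s for s in g["true_effect_size"].unique() if s > 1.0)
        results.append(
            PerformanceResult(
                design=design,
                variant=variant,
                type1=type1_error(g),
                type1_calibrated=type1_error(g, use_calibrated=True),
                type2={s: type2_error(g, s) for s in sizes},
                type2_calibrated={s: type2_error(g, s, use_calibrated=True) for s in sizes},
                months_to_50pct=time_to_sensitivity(g),
            )
        )
    return results


def performance_frame(results: list[PerformanceResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "design": r.design,
            "variant": r.variant,
            "type1": r.type1,
            "type1_calibrated": r.type1_calibrated,
        }
        for s, v in r.type2.items():
            row[f"type2_rr{s:g}"] = v
        for s, v in r.type2_calibrated.items():
            row[f"type2_calibrated_rr{s:g}"] = v
        for s, v in r.months_to_50pct.items():
            row[f"months_to_50pct_rr{s:g}"] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows)
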