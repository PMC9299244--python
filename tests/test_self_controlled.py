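"""SCCS/SCRI interval algebra, closed-form conditional estimates, invariances."""

import numpy as np
import pandas as pd
import pytest

from vaxsurv import SimulationConfig, simulate_tables
from vaxsurv._dates import to_day
from vaxsurv.self_controlled import (
    build_intervals,
    fit_sccs,
    fit_scri,
    run_self_controlled,
)


def _one_person_setup(vacc_day="2009-11-15", obs=("2008-09-01", "2010-05-31")):
    cfg = SimulationConfig(seed=0)
    vacc = pd.DataFrame({"person_id": [1], "date": [to_day(vacc_day)], "dose_number": [1]})
    periods = pd.DataFrame({"person_id": [1], "start": [to_day(obs[0])], "end": [to_day(obs[1])]})
    return cfg, vacc, periods


class TestBuildIntervals:
    def test_scri_pre_control_29_days_risk_28(self):
        cfg, vacc, periods = _one_person_setup()
        iv = build_intervals(vacc, periods, cfg, "scri_pre", cfg.study_window[1])
        lengths = iv.set_index("status").eval("end - start + 1")
        assert lengths["control"] == 29  # days -43..-15
        assert lengths["risk"] == 28  # days +1..+28

    def test_scri_post_window(self):
        cfg, vacc, periods = _one_person_setup()
        iv = build_intervals(vacc, periods, cfg, "scri_post", cfg.study_window[1])
        v = int(vacc["date"].iloc[0])
        ctl = iv[iv["status"] == "control"]
        assert ctl["start"].iloc[0] == v + 43 and ctl["end"].iloc[0] == v + 71

    def test_vaccination_on_observation_start_leaves_nothing_to_exclude(self):
        cfg, vacc, periods = _one_person_setup(vacc_day="2009-09-01")
        iv = build_intervals(vacc, periods, cfg, "sccs", cfg.study_window[1])
        v = int(vacc["date"].iloc[0])
        # no interval before the vaccination day; risk starts at +1
        assert iv["start"].min() == v + 1

    def test_sccs_pre_window_excluded(self):
        cfg, vacc, periods = _one_person_setup()
        iv = build_intervals(vacc, periods, cfg, "sccs", cfg.study_window[1])
        v = int(vacc["date"].iloc[0])
        for day in (v - 30, v - 1, v):
            inside = ((iv["start"] <= day) & (iv["end"] >= day)).any()
            assert not inside

    def test_two_close_doses_risk_takes_precedence(self):
        cfg, vacc, periods = _one_person_setup()
        v1 = int(vacc["date"].iloc[0])
        vacc2 = pd.DataFrame(
            {"person_id": [1, 1], "date": [v1, v1 + 28], "dose_number": [1, 2]}
        )
        iv = build_intervals(vacc2, periods, cfg, "sccs", cfg.study_window[1])
        risk = iv[iv["status"] == "risk"]
        # contiguous risk from v1+1 through v1+56; second dose's pre-exclusion
        # window (inside the first risk window) must NOT carve it up
        assert risk["start"].min() == v1 + 1
        assert risk["end"].max() == v1 + 28 + 28
        assert (risk["end"] - risk["start"] + 1).sum() == 56

    def test_intervals_disjoint_and_inside_study(self):
        cfg = SimulationConfig(n_persons=500, two_dose_fraction=0.5, dose_gap_days=40, seed=3)
        tables, _ = simulate_tables(cfg)
        for variant in ("sccs", "scri_pre", "scri_post", "sccs_all_pre"):
            iv = build_intervals(
                tables.vaccinations, tables.observation_periods, cfg, variant,
                cfg.study_window[1],
            )
            assert (iv["start"] >= cfg.study_window[0]).all()
            assert (iv["end"] <= cfg.study_window[1]).all()
            for _, g in iv.groupby("person_id"):
                g = g.sort_values("start")
                assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()


class TestFitSccs:
    def test_symmetric_two_intervals_give_irr_one(self):
        cfg, vacc, periods = _one_person_setup()
        iv = pd.DataFrame(
            {"person_id": [1, 1], "start": [100, 200], "end": [127, 227],
             "status": ["risk", "control"]}
        )
        ev = pd.DataFrame({"person_id": [1] * 4, "date": [105, 110, 205, 210]})
        rec = fit_sccs(iv, ev, cfg, look_cutoff=10_000)
        assert rec["log_estimate"] == pytest.approx(0.0, abs=1e-8)

    def test_two_interval_closed_form_irr_ten(self):
        # 2 events in 28 risk days vs 2 events in 280 control days:
        # conditional MLE = (2/28)/(2/280) = 10
        cfg, vacc, periods = _one_person_setup()
        iv = pd.DataFrame(
            {"person_id": [1, 1], "start": [100, 200], "end": [127, 479],
             "status": ["risk", "control"]}
        )
        ev = pd.DataFrame({"person_id": [1] * 4, "date": [105, 110, 205, 210]})
        rec = fit_sccs(iv, ev, cfg, look_cutoff=10_000)
        assert np.exp(rec["log_estimate"]) == pytest.approx(10.0, abs=1e-6)

    def test_no_risk_events_not_estimable(self):
        cfg, *_ = _one_person_setup()
        iv = pd.DataFrame(
            {"person_id": [1, 1], "start": [100, 200], "end": [127, 479],
             "status": ["risk", "control"]}
        )
        ev = pd.DataFrame({"person_id": [1], "date": [205]})
        rec = fit_sccs(iv, ev, cfg, look_cutoff=10_000)
        assert not rec["estimable"]

    def test_season_adjusted_agrees_with_unadjusted_when_no_seasonality(self):
        cfg = SimulationConfig(
            n_persons=20_000, n_negative_controls=2, baseline_rate=0.1,
            seasonal_amplitude=0.0, seed=4,
        )
        tables, defs = simulate_tables(cfg)
        oid = defs[0].outcome_id
        cut = cfg.study_window[1]
        rng = np.random.default_rng(0)
        un = run_self_controlled(tables, [oid], cfg, "sccs", cut, rng)
        ad = run_self_controlled(tables, [oid], cfg, "sccs_age_season", cut, rng)
        assert un["estimable"].iloc[0] and ad["estimable"].iloc[0]
        assert ad["log_estimate"].iloc[0] == pytest.approx(
            un["log_estimate"].iloc[0], abs=2.5 * un["se"].iloc[0]
        )

    def test_frailty_invariance(self):
        # per-person rate multipliers cancel in the conditional likelihood:
        # strong frailty with frailty-driven uptake leaves SCCS near the null
        cfg = SimulationConfig(
            n_persons=20_000, n_negative_controls=4, baseline_rate=0.08,
            frailty_sd=1.0, frailty_uptake_strength=0.8, seed=5,
        )
        tables, defs = simulate_tables(cfg)
        oids = [d.outcome_id for d in defs]
        df = run_self_controlled(tables, oids, cfg, "sccs", cfg.study_window[1],
                                 np.random.default_rng(0))
        est = df[df["estimable"]]
        pooled_se = est["se"].mean() / np.sqrt(len(est))
        assert abs(est["log_estimate"].mean()) < max(3 * pooled_se, 0.1)


class TestFitScri:
    def test_arithmetic_example(self):
        cfg, *_ = _one_person_setup()
        iv = pd.DataFrame(
            {"person_id": [1, 1], "start": [100, 200], "end": [127, 228],
             "status": ["risk", "control"]}  # 28 risk days, 29 control days
        )
        ev = pd.DataFrame({"person_id": [1] * 4, "date": [105, 110, 205, 210]})
        rec = fit_scri(iv, ev, cfg, look_cutoff=10_000)
        assert np.exp(rec["log_estimate"]) == pytest.approx((2 / 28) / (2 / 29), rel=1e-9)

    def test_zero_risk_events_boundary(self):
        cfg, *_ = _one_person_setup()
        iv = pd.DataFrame(
            {"person_id": [1, 1], "start": [100, 200], "end": [127, 228],
             "status": ["risk", "control"]}
        )
        ev = pd.DataFrame({"person_id": [1, 1], "date": [205, 210]})
        rec = fit_scri(iv, ev, cfg, look_cutoff=10_000)
        assert not rec["estimable"]
        assert np.isfinite(rec["ci_upper"])

    def test_swapping_interval_labels_inverts_irr(self):
        cfg, *_ = _one_person_setup()
        iv = pd.DataFrame(
            {"person_id": [1, 1], "start": [100, 200], "end": [127, 255],
             "status": ["risk", "control"]}
        )
        ev = pd.DataFrame({"person_id": [1] * 5, "date": [105, 110, 120, 205, 210]})
        fwd = fit_scri(iv, ev, cfg, look_cutoff=10_000)
        swapped = iv.assign(status=iv["status"].map({"risk": "control", "control": "risk"}))
        rev = fit_scri(swapped, ev, cfg, look_cutoff=10_000)
        assert fwd["log_estimate"] == pytest.approx(-rev["log_estimate"], rel=1e-9)

    def test_invariant_to_events_outside_both_intervals(self):
        cfg, *_ = _one_person_setup()
        iv = pd.DataFrame(
            {"person_id": [1, 1], "start": [100, 200], "end": [127, 228],
             "status": ["risk", "control"]}
        )
        ev1 = pd.DataFrame({"person_id": [1] * 2, "date": [105, 205]})
        ev2 = pd.DataFrame({"person_id": [1] * 4, "date": [105, 205, 500, 600]})
        r1 = fit_scri(iv, ev1, cfg, look_cutoff=10_000)
        r2 = fit_scri(iv, ev2, cfg, look_cutoff=10_000)
        assert r1["log_estimate"] == r2["log_estimate"]
        assert r1["p_one_sided"] == r2["p_one_sided"]
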