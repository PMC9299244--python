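"""Comparator sampling, propensity scores, adjustment, and the Cox outcome model."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import vaxsurv.cohort_method as cm
from vaxsurv import SimulationConfig


@pytest.fixture(scope="module")
def cohort_setup(confounded_tables):
    tables, defs, cfg = confounded_tables
    cut = cfg.study_window[1]
    rng = np.random.default_rng(17)
    vacc = cm.vaccinated_cohort(tables, cfg, cut)
    comp = cm.sample_comparator(tables, cfg, "visit", 4 * len(vacc), cut, rng)
    cohort = pd.concat([vacc, comp], ignore_index=True)
    X = cm.build_covariates(cohort, tables, cfg)
    return tables, cfg, cut, cohort, X


class TestSampleComparator:
    def test_visit_anchored_comparators_have_visit_on_index(self, cohort_setup):
        tables, cfg, cut, cohort, _ = cohort_setup
        comp = cohort[cohort["treated"] == 0]
        visits = set(zip(tables.visits["person_id"], tables.visits["date"]))
        pairs = list(zip(comp["person_id"], comp["index_date"]))
        assert all(p in visits for p in pairs)

    def test_no_comparator_vaccinated_on_or_before_index(self, cohort_setup):
        tables, cfg, cut, cohort, _ = cohort_setup
        comp = cohort[cohort["treated"] == 0]
        first = tables.vaccinations.groupby("person_id")["date"].min()
        fv = first.reindex(comp["person_id"]).to_numpy()
        assert not np.any(fv <= comp["index_date"].to_numpy())

    def test_random_anchor_index_in_observed_study_time(self, confounded_tables):
        tables, defs, cfg = confounded_tables
        cut = cfg.study_month_ends[4]
        comp = cm.sample_comparator(tables, cfg, "random_day", 500, int(cut),
                                    np.random.default_rng(3))
        assert (comp["index_date"] <= cut).all()
        assert (comp["index_date"] >= cfg.study_window[0]).all()
        per = tables.observation_periods.set_index("person_id")
        assert (comp["index_date"].to_numpy() >= per.loc[comp["person_id"], "start"].to_numpy()).all()
        assert (comp["index_date"].to_numpy() <= per.loc[comp["person_id"], "end"].to_numpy()).all()

    def test_shortfall_returns_all_available(self, confounded_tables):
        tables, defs, cfg = confounded_tables
        comp = cm.sample_comparator(tables, cfg, "visit", 10**7, cfg.study_window[1],
                                    np.random.default_rng(0))
        assert len(comp) < 10**7
        assert comp["person_id"].is_unique


class TestCovariates:
    def test_empty_history_leaves_only_demographics(self, confounded_tables):
        tables, defs, cfg = confounded_tables
        # a person with no visits or outcomes before index
        busy = set(tables.visits["person_id"]) | set(tables.outcomes["person_id"])
        quiet = tables.persons.loc[~tables.persons["person_id"].isin(busy), "person_id"]
        if len(quiet) == 0:
            pytest.skip("no event-free person in this draw")
        cohort = pd.DataFrame(
            {"person_id": [quiet.iloc[0]], "index_date": [cfg.study_window[0] + 40],
             "treated": [1]}
        )
        X = cm.build_covariates(cohort, tables, cfg)
        hist_cols = [c for c in X.columns if c.startswith("hist_")]
        assert X[hist_cols].to_numpy().sum() == 0 if hist_cols else True
        assert X["log_visits"].iloc[0] == 0.0

    def test_no_post_index_information(self, confounded_tables):
        tables, defs, cfg = confounded_tables
        # a visit on or after the index date must not enter the lookback count
        v = tables.visits.iloc[len(tables.visits) // 2]
        for offset, counted in [(0, False), (1, True), (400, False)]:
            cohort = pd.DataFrame(
                {"person_id": [v["person_id"]], "index_date": [v["date"] + offset],
                 "treated": [1]}
            )
            X = cm.build_covariates(cohort, tables, cfg)
            pid_visits = tables.visits[tables.visits["person_id"] == v["person_id"]]
            in_window = (
                (pid_visits["date"] < v["date"] + offset)
                & (pid_visits["date"] >= v["date"] + offset - 365)
            ).sum()
            assert X["log_visits"].iloc[0] == pytest.approx(np.log1p(in_window))
            if counted:
                assert in_window >= 1


class TestPropensity:
    def test_null_covariates_give_auc_half(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10_000, 5)), columns=list("abcde"))
        treated = rng.random(10_000) < 0.3
        ps = cm.fit_propensity(X, treated, seed=0)
        assert abs(roc_auc_score(treated, ps) - 0.5) < 0.03

    def test_perfect_separation_is_regularised(self):
        rng = np.random.default_rng(2)
        treated = (rng.random(500) < 0.5).astype(int)
        X = pd.DataFrame({"sep": treated.astype(float), "noise": rng.normal(size=500)})
        ps = cm.fit_propensity(X, treated, seed=0)
        assert np.all((ps > 0) & (ps < 1))

    def test_confounded_uptake_gives_auc_above_half(self, cohort_setup):
        tables, cfg, cut, cohort, X = cohort_setup
        ps = cm.fit_propensity(X, cohort["treated"].to_numpy(), seed=0)
        assert roc_auc_score(cohort["treated"], ps) > 0.55


class TestAdjustment:
    def test_identical_ps_matches_all_vaccinated(self):
        cohort = pd.DataFrame(
            {"person_id": np.arange(200), "index_date": 100, "treated": [1] * 100 + [0] * 100}
        )
        rng = np.random.default_rng(0)
        ps = 0.5 + rng.normal(0, 1e-4, 200)  # same PS distribution in both arms
        matched = cm.match_on_ps(cohort, ps)
        # greedy caliper matching loses a few treated at the density tails
        assert (matched["treated"] == 1).sum() >= 80
        # and every retained pair is within the caliper
        logit = np.log(ps / (1 - ps))
        by_set = matched.groupby("match_id").apply(
            lambda g: abs(np.diff(logit[g.index])[0]), include_groups=False
        )
        assert (by_set <= 0.2 * np.std(logit) + 1e-12).all()

    def test_matching_balances_covariates(self, cohort_setup):
        tables, cfg, cut, cohort, X = cohort_setup
        ps = cm.fit_propensity(X, cohort["treated"].to_numpy(), seed=0)
        matched = cm.match_on_ps(cohort, ps)
        t = matched[matched["treated"] == 1].index
        c = matched[matched["treated"] == 0].index
        for col in ("age", "sex_F", "log_visits"):
            pooled_sd = X[col].std()
            if pooled_sd == 0:
                continue
            smd = abs(X.loc[t, col].mean() - X.loc[c, col].mean()) / pooled_sd
            assert smd < 0.1, col

    def test_att_weight_formula_point(self):
        cohort = pd.DataFrame(
            {"person_id": [1, 2], "index_date": [10, 10], "treated": [1, 0]}
        )
        out = cm.att_weights(cohort, np.array([0.7, 0.5]))
        assert out["weight"].tolist() == [1.0, 1.0]  # 0.5/(1-0.5) = 1

    def test_stratification_drops_one_armed_strata(self):
        cohort = pd.DataFrame(
            {"person_id": np.arange(100), "index_date": 10,
             "treated": [1] * 50 + [0] * 50}
        )
        # all treated at high PS: lowest quintiles contain only comparators
        ps = np.r_[np.linspace(0.8, 0.99, 50), np.linspace(0.01, 0.2, 50)]
        out = cm.stratify_on_ps(cohort, ps)
        for _, g in out.groupby("stratum"):
            assert g["treated"].nunique() == 2


class TestEstimateHr:
    def test_identical_arms_give_unit_hazard_ratio(self):
        pop = pd.DataFrame(
            {
                "treated": [1, 1, 1, 0, 0, 0],
                "time": [5.0, 12.0, 28.0, 5.0, 12.0, 28.0],
                "event": [1, 1, 0, 1, 1, 0],
            }
        )
        rec = cm.estimate_hr(pop)
        assert rec["log_estimate"] == pytest.approx(0.0, abs=1e-6)

    def test_three_person_partial_likelihood_brute_force(self):
        # events at t=3 (treated) and t=7 (untreated), one censored treated at 10
        pop = pd.DataFrame(
            {"treated": [1, 0, 1], "time": [3.0, 7.0, 10.0], "event": [1, 1, 0]}
        )
        rec = cm.estimate_hr(pop)
        betas = np.linspace(-4, 4, 400_001)
        # partial likelihood: e^b/(2e^b+1) * 1/(e^b+1)
        ll = betas - np.log(2 * np.exp(betas) + 1) - np.log(np.exp(betas) + 1)
        brute = betas[np.argmax(ll)]
        assert rec["log_estimate"] == pytest.approx(brute, abs=1e-5)

    def test_rank_invariance_under_time_scaling(self):
        rng = np.random.default_rng(3)
        pop = pd.DataFrame(
            {
                "treated": rng.integers(0, 2, 60),
                "time": rng.uniform(1, 28, 60).round(3),
                "event": rng.integers(0, 2, 60),
            }
        )
        r1 = cm.estimate_hr(pop)
        r2 = cm.estimate_hr(pop.assign(time=pop["time"] * 2))
        assert r1["log_estimate"] == pytest.approx(r2["log_estimate"], rel=1e-8)

    def test_zero_events_in_one_arm_not_estimable(self):
        pop = pd.DataFrame(
            {"treated": [1, 1, 0, 0], "time": [5.0, 8.0, 28.0, 28.0], "event": [1, 1, 0, 0]}
        )
        rec = cm.estimate_hr(pop)
        assert not rec["estimable"]
        assert rec["events_exposed"] == 2 and rec["events_comparator"] == 0


class TestAnchorBias:
    def test_bias_sign_flips_with_comparator_anchor(self, confounded_tables):
        tables, defs, cfg = confounded_tables
        oids = [d.outcome_id for d in defs]
        cut = cfg.study_window[1]
        rng = np.random.default_rng(5)
        visit = cm.run_cohort(tables, oids, cfg, "unadj_visit", cut, rng)
        rand = cm.run_cohort(tables, oids, cfg, "unadj_random", cut, rng)
        mv = visit.loc[visit["estimable"], "log_estimate"].mean()
        mr = rand.loc[rand["estimable"], "log_estimate"].mean()
        assert mr > mv
        assert mr > 0


def test_per_month_matching_preserved_across_looks(confounded_tables):
    tables, defs, cfg = confounded_tables
    oids = [defs[0].outcome_id]
    state = {}
    looks = cfg.study_month_ends
    rng1 = np.random.default_rng(7)
    cm.run_cohort(tables, oids, cfg, "ps_month_match_visit", int(looks[2]), rng1, state=state)
    frozen = state["ps_month_match_visit"].copy()
    rng2 = np.random.default_rng(8)
    cm.run_cohort(tables, oids, cfg, "ps_month_match_visit", int(looks[4]), rng2, state=state)
    later = state["ps_month_match_visit"]
    early_months = set(frozen["match_month"])
    kept = later[later["match_month"].isin(early_months)]
    pd.testing.assert_frame_equal(
        kept.sort_values(["match_id", "treated"]).reset_index(drop=True)[frozen.columns],
        frozen.sort_values(["match_id", "treated"]).reset_index(drop=True),
    )
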