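"""Grid orchestration, performance metrics, plots, and the CLI surface."""

import numpy as np
import pandas as pd
import pytest

import vaxsurv
from vaxsurv import (
    SimulationConfig,
    performance_frame,
    run_grid,
    simulate_tables,
    summarize,
    time_to_sensitivity,
    type1_error,
    type2_error,
)
from vaxsurv.estimates import make_record, records_frame


@pytest.fixture(scope="module")
def small_grid(null_tables):
    tables, defs, cfg = null_tables
    variants = [("historical_comparator", "unadj"), ("self_controlled", "sccs")]
    looks = cfg.study_month_ends[2::3]  # 3 looks
    est = run_grid(tables, defs, cfg, variants=variants, looks=looks, cv_mc_reps=4000)
    return est, tables, defs, cfg, variants, looks


class TestRunGrid:
    def test_record_counting(self, small_grid):
        est, tables, defs, cfg, variants, looks = small_grid
        # 2 variants x 6 outcomes x 3 looks base records, plus 3 imputed
        # positives for every estimable negative
        base = est[est["outcome_id"] == est["parent_outcome"]]
        assert len(base) == 2 * 6 * 3
        n_estimable_neg = int(base["estimable"].sum())
        assert len(est) == len(base) + 3 * n_estimable_neg

    def test_rerun_is_identical(self, null_tables, small_grid):
        est, tables, defs, cfg, variants, looks = small_grid
        est2 = run_grid(tables, defs, cfg, variants=variants, looks=looks, cv_mc_reps=4000)
        pd.testing.assert_frame_equal(est, est2)

    def test_no_silent_gaps(self, small_grid):
        est, tables, defs, cfg, variants, looks = small_grid
        base = est[est["outcome_id"] == est["parent_outcome"]]
        cells = base.groupby(["design", "variant", "outcome_id"])["look_month"].nunique()
        assert (cells == len(looks)).all()

    def test_final_look_matches_whole_period_run(self, null_tables, small_grid):
        est, tables, defs, cfg, variants, looks = small_grid
        from vaxsurv.historical_comparator import run_historical

        final = est[
            (est["design"] == "historical_comparator")
            & (est["look_month"] == len(looks))
            & (est["outcome_id"] == est["parent_outcome"])
        ].sort_values("outcome_id")
        whole = run_historical(
            tables, sorted(d.outcome_id for d in defs), cfg, "unadj", int(looks[-1])
        )
        np.testing.assert_allclose(
            final["log_estimate"].to_numpy(), whole["log_estimate"].to_numpy()
        )

    def test_llr_and_cv_attached(self, small_grid):
        est, *_ = small_grid
        ok = est[est["estimable"]]
        assert ok["llr"].notna().all()
        assert (ok["llr"] >= 0).all()
        assert ok["cv"].notna().all()
        assert (ok["cv"] > 0).all()

    def test_calibrated_columns_populated(self, small_grid):
        est, *_ = small_grid
        ok = est[est["estimable"]]
        assert ok["p_calibrated"].notna().all()
        assert ok["p_calibrated"].between(0, 1).all()
        assert (ok["llr_calibrated"] >= 0).all()


def _records(p_values, effect=1.0, estimable=True, llr=None, cv=1.0, look=1):
    rows = []
    for i, p in enumerate(p_values):
        rows.append(
            make_record(
                design="d", variant="v", outcome_id=f"o{i}", true_effect_size=effect,
                look_month=look, p_one_sided=p, p_calibrated=p, estimable=estimable,
                llr=llr[i] if llr is not None else 0.0,
                llr_calibrated=llr[i] if llr is not None else 0.0, cv=cv,
                log_estimate=0.0, se=1.0,
            )
        )
    return records_frame(rows)


class TestMetrics:
    def test_type1_zero_when_all_p_half(self):
        assert type1_error(_records([0.5] * 10)) == 0.0

    def test_type1_near_alpha_for_uniform_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(93 * 20)
        t1 = type1_error(_records(p))
        assert abs(t1 - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(p))

    def test_degenerate_threshold(self):
        recs = _records([0.5, 0.9, 0.3])
        assert (recs["p_one_sided"] < 1.0).mean() == 1.0

    def test_type2_zero_when_all_rejected(self):
        assert type2_error(_records([0.001] * 5, effect=2.0), 2.0) == 0.0

    def test_type2_nan_without_positives(self):
        assert np.isnan(type2_error(_records([0.5] * 5), 2.0))

    def test_type2_monotone_in_effect_size_by_construction(self, small_grid):
        est, *_ = small_grid
        t2 = {k: type2_error(est, k) for k in (1.5, 2.0, 4.0)}
        assert t2[1.5] >= t2[2.0] >= t2[4.0]

    def test_time_to_sensitivity_all_signal_at_look_one(self):
        recs = pd.concat(
            [_records([0.01] * 4, effect=2.0, llr=[5.0] * 4, look=l) for l in (1, 2, 3)],
            ignore_index=True,
        )
        assert time_to_sensitivity(recs)[2.0] == 1

    def test_time_to_sensitivity_half_at_look_three(self):
        frames = []
        for look in (1, 2, 3):
            llrs = [5.0 if (i < 2 and look >= 3) else 0.0 for i in range(4)]
            frames.append(_records([0.5] * 4, effect=2.0, llr=llrs, look=look))
        recs = pd.concat(frames, ignore_index=True)
        out = time_to_sensitivity(recs)
        assert out[2.0] == 3

    def test_time_to_sensitivity_never(self):
        recs = _records([0.5] * 4, effect=2.0, llr=[0.0] * 4)
        assert time_to_sensitivity(recs)[2.0] is None

    def test_retargeting_to_80pct(self):
        frames = []
        for look in (1, 2):
            llrs = [5.0 if (i < 2 and look >= 1) else 0.0 for i in range(4)]
            frames.append(_records([0.5] * 4, effect=2.0, llr=llrs, look=look))
        recs = pd.concat(frames, ignore_index=True)
        assert time_to_sensitivity(recs, target=0.5)[2.0] == 1
        assert time_to_sensitivity(recs, target=0.8)[2.0] is None

    def test_summarize_one_result_per_variant(self, small_grid):
        est, *_ = small_grid
        results = summarize(est)
        assert len(results) == est.groupby(["design", "variant"]).ngroups
        frame = performance_frame(results)
        assert {"design", "variant", "type1", "type1_calibrated"} <= set(frame.columns)
        assert frame["type1"].between(0, 1).all()


def test_plots_written(tmp_path, small_grid):
    est, *_ = small_grid
    from vaxsurv.plots import write_all_plots

    perf = performance_frame(summarize(est))
    paths = write_all_plots(est, perf, tmp_path)
    for p in paths:
        assert p.exists() and p.stat().st_size > 0


class TestCli:
    def test_simulate_and_estimate_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from vaxsurv.cli import main

        cfg = SimulationConfig(n_persons=400, n_negative_controls=3, baseline_rate=0.3, seed=5)
        cfg_path = tmp_path / "config.json"
        cfg_path.write_text(cfg.to_json())
        runner = CliRunner()
        res = runner.invoke(
            main, ["simulate", "--config", str(cfg_path), "--out", str(tmp_path / "tables")]
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "tables" / "person.csv").exists()

        res = runner.invoke(
            main,
            [
                "estimate",
                "--tables", str(tmp_path / "tables"),
                "--variants", "historical_comparator/unadj",
                "--out", str(tmp_path / "estimates.csv"),
            ],
        )
        assert res.exit_code == 0, res.output
        est = pd.read_csv(tmp_path / "estimates.csv")
        assert len(est) > 0

        res = runner.invoke(
            main,
            ["evaluate", "--estimates", str(tmp_path / "estimates.csv"),
             "--out", str(tmp_path / "metrics")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "metrics" / "performance.csv").exists()

    def test_unknown_variant_is_config_error(self, tmp_path):
        from click.testing import CliRunner

        from vaxsurv.cli import main

        runner = CliRunner()
        (tmp_path / "t").mkdir()
        res = runner.invoke(
            main,
            ["estimate", "--tables", str(tmp_path), "--variants", "bogus",
             "--out", str(tmp_path / "x.csv")],
        )
        assert res.exit_code == 2
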