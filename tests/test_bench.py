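"""Tests of the benchmark orchestration, truth tables, reporting and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from causaltrio import bench
from causaltrio.bench import (BenchConfig, TRUTH, run_scenario, run_sweep,
                              summarize_scores, tidy_summaries)
from causaltrio.cli import main as cli_main
from causaltrio.simulate import SCENARIO_IDS

FAST = BenchConfig(cit_b_perm=100)


class TestTruthTables:
    def test_correct_model_map(self):
        expect = {s: s for s in "abcdefg"}
        expect.update({"h": "a", "i": "b", "j": "c", "k": "m", "l": "n"})
        assert dict(TRUTH.correct_model) == expect

    def test_mr_truth_is_the_x_to_y_scenarios(self):
        # derived from the generative equations, checked against the
        # hand-enumerated set of structures containing an X -> Y arrow
        assert TRUTH.mr_true == frozenset({"b", "d", "g", "i"})

    def test_cit_truth_is_the_pure_chains(self):
        assert TRUTH.cit_true == frozenset({"b", "i"})

    def test_testable_sets(self):
        assert set(TRUTH.sem_testable) == {"a", "b", "c", "f", "g"}
        assert set(TRUTH.buf_testable) == {"a", "b", "c", "m", "n"}


class TestRunScenario:
    def test_bitwise_reproducible(self):
        kw = dict(methods=["mr", "sem", "buf"], n_reps=6, base_seed=42)
        r1 = run_scenario("h", **kw)
        r2 = run_scenario("h", **kw)
        for m in kw["methods"]:
            assert r1[m].to_dict() == r2[m].to_dict()
        r3 = run_scenario("h", methods=["mr"], n_reps=6, base_seed=43)
        assert r3["mr"].to_dict() != r1["mr"].to_dict()

    def test_selection_rates_partition_unity(self):
        res = run_scenario("b", ["sem", "buf", "bnlearn", "deal"], n_reps=25,
                           base_seed=1)
        for m, s in res.items():
            total = (s.correct_rate + s.incorrect_rate + s.tie_rate
                     + s.failure_rate)
            assert total == pytest.approx(1.0)
            assert sum(s.selection_counts.values()) + s.failure_rate * s.n_reps \
                == s.n_reps

    def test_detection_summary_fields(self):
        res = run_scenario("b", ["mr"], n_reps=30, base_seed=2)["mr"]
        assert res.true_detection is True
        assert 0.0 <= res.detection_rate <= 1.0
        res_a = run_scenario("a", ["mr"], n_reps=5, base_seed=2)["mr"]
        assert res_a.true_detection is False

    def test_sem_not_applicable_under_k(self):
        res = run_scenario("k", ["sem"], n_reps=10, base_seed=3)["sem"]
        assert res.correct_rate is None and res.incorrect_rate is None
        assert res.selection_counts  # distribution still reported

    def test_validation(self):
        with pytest.raises(ValueError):
            run_scenario("b", [], n_reps=5)
        with pytest.raises(ValueError):
            run_scenario("b", ["mr"], n_reps=0)
        with pytest.raises(ValueError):
            run_scenario("b", ["magic"], n_reps=5)


class TestSweep:
    def test_sweep_runs_and_tags_values(self):
        out = run_sweep("gamma", [0.5, 1.0], "b", ["mr"], n_reps=8, base_seed=4)
        assert len(out) == 2
        assert [s.config["sweep"]["value"] for s in out] == [0.5, 1.0]

    def test_sweep_validation(self):
        with pytest.raises(ValueError):
            run_sweep("zeta", [1.0], "b", ["mr"], n_reps=2)  # no E in (b)
        with pytest.raises(ValueError):
            run_sweep("omega", [1.0], "b", ["mr"], n_reps=2)
        with pytest.raises(ValueError):
            run_sweep("gamma", [], "b", ["mr"], n_reps=2)

    def test_stronger_confounding_degrades_selection(self):
        # under confounded mediation (i), a stronger latent effect drags
        # every selection method away from the correct structure
        out = run_sweep("zeta", [0.5, 2.0], "i", ["sem", "bnlearn"],
                        n_reps=60, base_seed=21)
        rates = {(s.method, s.config["sweep"]["value"]): s.correct_rate
                 for s in out}
        assert rates[("sem", 2.0)] < rates[("sem", 0.5)]
        assert rates[("bnlearn", 2.0)] < rates[("bnlearn", 0.5)]

    def test_power_collapses_at_tiny_effect(self):
        out = run_sweep("gamma", [0.005, 1.0], "b", ["mr"], n_reps=40,
                        base_seed=5)
        low, high = (s.detection_rate for s in out)
        assert low < 0.4 < high


@pytest.fixture(scope="module")
def summaries():
    return bench.run_benchmark(SCENARIO_IDS, ["sem", "buf"], n_reps=3,
                               base_seed=6)


class TestReporting:
    def test_score_matrix_shapes(self, summaries):
        mats = summarize_scores(summaries)
        assert mats["sem"].shape == (5, 12)
        assert list(mats["sem"].index) == ["a", "b", "c", "f", "g"]
        assert mats["buf"].shape == (5, 12)
        assert list(mats["buf"].index) == ["a", "b", "c", "m", "n"]
        assert list(mats["sem"].columns) == list(SCENARIO_IDS)

    def test_empty_input(self):
        assert summarize_scores([]) == {}
        assert tidy_summaries([]).empty

    def test_tidy_layout(self, summaries):
        df = tidy_summaries(summaries)
        assert set(df.columns) >= {"scenario", "method", "statistic", "value"}
        assert len(df[df.statistic == "correct_rate"]) > 0


class TestCli:
    def test_simulate_run_report_cycle(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate", "--scenario", "b", "--reps",
                                     "2", "--n", "50", "--seed", "1",
                                     "--out", str(tmp_path / "sim")])
        assert r.exit_code == 0, r.output
        files = sorted((tmp_path / "sim").glob("*.csv"))
        assert len(files) == 2

        out = tmp_path / "bench.json"
        r = runner.invoke(cli_main, ["run", "--scenario", "b", "--methods",
                                     "mr,sem", "--reps", "4", "--seed", "1",
                                     "--out", str(out)])
        assert r.exit_code == 0, r.output
        payload = json.loads(out.read_text())
        assert {d["method"] for d in payload} == {"mr", "sem"}

        r = runner.invoke(cli_main, ["report", "--in", str(out), "--out",
                                     str(tmp_path / "rep")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "rep_tidy.csv").exists()
        assert (tmp_path / "rep_scores_sem.csv").exists()

    def test_sweep_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sweep.json"
        r = runner.invoke(cli_main, ["sweep", "--scenario", "b", "--param",
                                     "alpha", "--values", "0.5,1", "--methods",
                                     "mr", "--reps", "3", "--seed", "2",
                                     "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert len(json.loads(out.read_text())) == 2
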