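import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from samplingcost import (
    GeneratorConfig,
    RunConfig,
    generate_rt_dataset,
    read_rt_table,
    run_demo_pipeline,
    write_rt_table,
)
from samplingcost.cli import main
from samplingcost.pipeline import dump_config, load_config


class TestRTTableIO:
    def test_handwritten_round_trip(self, tmp_path):
        path = tmp_path / "rt.tsv"
        path.write_text(
            "subject_id\titem_id\tsurprisal\trt\n"
            "s0\t0\t1.5\t310.0\n"
            "s0\t1\t2.25\t295.5\n"
            "s1\t0\t1.5\t402.0\n"
        )
        data = read_rt_table(path)
        assert len(data) == 3
        assert data.frame["rt"].tolist() == [310.0, 295.5, 402.0]
        # prev_surprisal derived from item order within subject
        s0 = data.frame[data.frame["subject_id"] == "s0"].sort_values("item_id")
        assert s0["prev_surprisal"].tolist() == [0.0, 1.5]

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("subject_id\titem_id\tsurprisal\ns0\t0\t1.0\n")
        with pytest.raises(ValueError, match="rt"):
            read_rt_table(path)

    def test_generated_round_trip_is_value_identical(self, tmp_path):
        data = generate_rt_dataset(GeneratorConfig(seed=8, n_subjects=10, n_items=100))
        path = tmp_path / "gen.tsv"
        write_rt_table(data, path)
        back = read_rt_table(path)
        for col in ("surprisal", "prev_surprisal", "rt"):
            np.testing.assert_allclose(back.frame[col], data.frame[col])


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=9, n_items=123)
        path = tmp_path / "cfg.yaml"
        dump_config(cfg, path)
        assert load_config(path) == cfg


@pytest.fixture(scope="module")
def small_cfg(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo")
    return RunConfig(
        families={
            "linear": {"family": "linear", "params": {"alpha": 250.0, "beta": 25.0}},
            "power2": {"family": "power", "params": {"c": 15.0, "k": 2.0}},
        },
        n_subjects=25,
        n_items=300,
        seed=17,
        outdir=str(out),
    )


class TestDemoPipeline:
    def test_report_shapes_and_signs(self, small_cfg):
        report = run_demo_pipeline(small_cfg)
        lin = report["families"]["linear"]
        convex = report["families"]["power2"]
        assert lin["beta_mean"] > 0
        # linear-link superlinearity is small relative to the convex link's
        assert abs(lin["superlinearity"]) < convex["superlinearity"]
        assert convex["superlinearity"] > 0

    def test_report_is_deterministic(self, small_cfg, tmp_path):
        from dataclasses import replace

        a = run_demo_pipeline(replace(small_cfg, outdir=str(tmp_path / "a")))
        b = run_demo_pipeline(replace(small_cfg, outdir=str(tmp_path / "b")))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


class TestCLI:
    def test_theory_subcommand(self, tmp_path):
        runner = CliRunner()
        wpath = tmp_path / "w.tsv"
        wpath.write_text("weight\n0.4\n0.3\n0.2\n0.1\n")
        out = tmp_path / "theory.tsv"
        result = runner.invoke(main, ["theory", "--weights", str(wpath), "--out", str(out)])
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out, sep="\t")
        assert set(table.columns) >= {"surprisal_nats", "mean_wr", "var_wr", "mean_wor", "var_wor"}
        row = table[table["item"] == 0].iloc[0]
        assert row["mean_wor"] == pytest.approx(1.96190, abs=1e-4)
        assert row["mean_wr"] == pytest.approx(2.5)

    def test_simulate_subcommand(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim.tsv"
        result = runner.invoke(
            main,
            ["simulate", "--pareto", "20", "1", "1", "--runs", "200", "--seed", "3", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert len(pd.read_csv(out, sep="\t")) == 20

    def test_synth_fit_superlinearity_chain(self, tmp_path):
        runner = CliRunner()
        data_path = tmp_path / "data.tsv"
        r1 = runner.invoke(main, ["synth", "--seed", "5", "--out", str(data_path)])
        assert r1.exit_code == 0, r1.output
        prefix = tmp_path / "fit"
        r2 = runner.invoke(main, ["fit", "--in", str(data_path), "--out-prefix", str(prefix)])
        assert r2.exit_code == 0, r2.output
        curve = pd.read_csv(f"{prefix}.tsv", sep="\t")
        assert {"grid", "mu", "log_sd"} <= set(curve.columns)
        r3 = runner.invoke(
            main, ["superlinearity", "--in", f"{prefix}.tsv", "--x-col", "grid", "--y-col", "mu"]
        )
        assert r3.exit_code == 0, r3.output
        payload = json.loads(r3.output)
        assert "superlinearity" in payload

    def test_degrade_subcommand(self, tmp_path):
        runner = CliRunner()
        data_path = tmp_path / "data.tsv"
        runner.invoke(main, ["synth", "--seed", "5", "--out", str(data_path)])
        out = tmp_path / "deg.tsv"
        r = runner.invoke(
            main,
            ["degrade", "--in", str(data_path), "--fraction", "0.3", "--inflation", "2",
             "--seed", "1", "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        a = pd.read_csv(data_path, sep="\t")
        b = pd.read_csv(out, sep="\t")
        assert (a["surprisal"] != b["surprisal"]).sum() > 0
        np.testing.assert_allclose(a["rt"], b["rt"])

    def test_trend_subcommand(self, tmp_path):
        runner = CliRunner()
        path = tmp_path / "pts.tsv"
        pd.DataFrame(
            {"quality": [-3.0, -2.5, -2.0], "superlinearity": [1.0, 2.0, 3.0]}
        ).to_csv(path, sep="\t", index=False)
        r = runner.invoke(main, ["trend", "--in", str(path)])
        assert r.exit_code == 0, r.output
        payload = json.loads(r.output)
        assert payload["slope"] == pytest.approx(2.0)
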