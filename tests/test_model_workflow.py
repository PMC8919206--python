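import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from refstab.cli import main as cli_main
from refstab.cq import CqMatrix, write_replicate_table
from refstab.model import ReferenceGeneStability, StandardCurve
from refstab.simulate import SimulationConfig, generate_cq_experiment
from refstab.workflow import WorkflowConfig, run_stability_workflow, write_report


@pytest.fixture(scope="module")
def experiment():
    return generate_cq_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="module")
def long_tsv(experiment, tmp_path_factory):
    p = tmp_path_factory.mktemp("data") / "cq_long.tsv"
    write_replicate_table(experiment.replicates, p)
    return p


class TestModelFacade:
    def test_fit_produces_all_method_tables(self, experiment):
        res = ReferenceGeneStability.from_replicates(experiment.replicates).fit()
        assert set(res.method_results) == {"genorm", "normfinder",
                                           "bestkeeper", "deltact"}
        assert res.aggregate is not None
        assert len(res.ranking) == 12
        assert res.v_profile is not None and set(res.v_profile.v_values) == \
            set(range(2, 12))

    def test_ranking_tracks_true_noise_order(self, experiment):
        res = ReferenceGeneStability.from_replicates(experiment.replicates).fit()
        # lowest-noise gene among the top of the comprehensive ranking
        assert experiment.truth.stability_order[0] in res.ranking[:2]

    def test_summary_contains_values_and_recommendation(self, experiment):
        res = ReferenceGeneStability.from_replicates(experiment.replicates).fit()
        text = res.summary()
        assert "genorm" in text and "recommended number" in text
        for g in res.ranking[:3]:
            assert g in text

    def test_missing_sample_dropped_before_analysis(self, experiment):
        from refstab.cq import average_technical_replicates
        m = average_technical_replicates(experiment.replicates)
        vals = m.values.copy()
        vals.iloc[0, 0] = np.nan
        model = ReferenceGeneStability(CqMatrix(vals))
        assert model.cq.n_samples == 35

    def test_subset_of_methods(self, experiment):
        res = ReferenceGeneStability.from_replicates(experiment.replicates).fit(
            ["deltact"])
        assert res.aggregate is None
        assert any("skipped" in w for w in res.warnings)
        assert res.ranking  # falls back to the single method's order

    def test_standard_curve_results_surface(self):
        x = np.arange(4.0, 10.0)
        y = 40.0 - (1 / np.log10(2.0)) * x
        res = StandardCurve(x, y, gene="EF1A").fit()
        assert res.efficiency_percent == pytest.approx(100.0, abs=1e-9)
        assert "EF1A" in res.summary()
        assert "100.00" in res.summary()


class TestWorkflow:
    def test_end_to_end_writes_expected_files(self, long_tsv, tmp_path):
        cfg = WorkflowConfig(input_path=str(long_tsv), layout="long",
                             output_dir=str(tmp_path / "out"))
        report = run_stability_workflow(cfg)
        written = write_report(report, cfg.output_dir)
        names = {p.name for p in written}
        assert names == {"genorm.tsv", "normfinder.tsv", "bestkeeper.tsv",
                         "deltact.tsv", "aggregate.tsv",
                         "pairwise_variation.tsv", "report.json"}
        meta = json.loads((tmp_path / "out" / "report.json").read_text())
        assert meta["config"]["layout"] == "long"
        assert len(meta["ranking"]) == 12

    def test_reports_are_deterministic(self, long_tsv, tmp_path):
        outs = []
        for sub in ("a", "b"):
            cfg = WorkflowConfig(input_path=str(long_tsv), layout="long",
                                 output_dir=str(tmp_path / sub))
            write_report(run_stability_workflow(cfg), cfg.output_dir)
            outs.append({p.name: p.read_bytes()
                         for p in sorted((tmp_path / sub).iterdir())
                         if p.name != "report.json"})
        assert outs[0] == outs[1]

    def test_written_tables_round_trip(self, long_tsv, tmp_path):
        cfg = WorkflowConfig(input_path=str(long_tsv), layout="long",
                             output_dir=str(tmp_path / "rt"))
        report = run_stability_workflow(cfg)
        write_report(report, cfg.output_dir)
        df = pd.read_csv(tmp_path / "rt" / "deltact.tsv", sep="\t")
        mem = report.results.method_table("deltact")
        assert list(df["gene"]) == list(mem["gene"])
        assert df["stability"].to_numpy() == pytest.approx(
            mem["stability"].to_numpy(), rel=1e-5)

    def test_deltact_only_skips_aggregate(self, long_tsv, tmp_path):
        cfg = WorkflowConfig(input_path=str(long_tsv), layout="long",
                             methods=("deltact",),
                             output_dir=str(tmp_path / "one"))
        report = run_stability_workflow(cfg)
        written = write_report(report, cfg.output_dir)
        names = {p.name for p in written}
        assert "deltact.tsv" in names and "aggregate.tsv" not in names


class TestCli:
    def test_stability_command(self, long_tsv, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cli_out"
        result = runner.invoke(cli_main, [
            "stability", "--input", str(long_tsv), "--layout", "long",
            "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert (out / "aggregate.tsv").exists()
        assert "recommended number" in result.output

    def test_curve_command(self, tmp_path):
        curve = tmp_path / "curve.tsv"
        lines = ["gene\tlog10_amount\tcq"]
        for x in range(4, 10):
            lines.append(f"EF1A\t{x}\t{40 - 3.321928 * x:.6f}")
        curve.write_text("\n".join(lines) + "\n")
        runner = CliRunner()
        result = runner.invoke(cli_main, ["curve", "--input", str(curve),
                                          "--out", str(tmp_path / "fits.tsv")])
        assert result.exit_code == 0, result.output
        fits = pd.read_csv(tmp_path / "fits.tsv", sep="\t")
        assert fits.loc[0, "efficiency_percent"] == pytest.approx(100.0, abs=1e-3)

    def test_simulate_then_stability_pipeline(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        r1 = runner.invoke(cli_main, ["simulate", "--seed", "5",
                                      "--out", str(sim_dir)])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(cli_main, [
            "stability", "--input", str(sim_dir / "cq_long.tsv"),
            "--layout", "long", "--out", str(tmp_path / "res")])
        assert r2.exit_code == 0, r2.output

    def test_aggregate_command_checks_expected_order(self, tmp_path):
        from refstab.aggregate import (load_published_orderings,
                                       published_rank_table)
        table = published_rank_table("starvation").reset_index()
        ranks = tmp_path / "ranks.tsv"
        table.to_csv(ranks, sep="\t", index=False)
        expected = tmp_path / "expected.txt"
        expected.write_text("\n".join(load_published_orderings()["starvation"]))
        runner = CliRunner()
        result = runner.invoke(cli_main, ["aggregate", "--ranks", str(ranks),
                                          "--expected", str(expected),
                                          "--out", str(tmp_path / "agg.tsv")])
        assert result.exit_code == 0, result.output
        assert "matches expected ordering" in result.output
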