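import numpy as np
import pytest
from click.testing import CliRunner

from batfruitnet import (
    GeneratorConfig,
    NetworkSummary,
    analyze_network,
    generate_network,
    load_field_summaries,
    summarize_suite,
)
from batfruitnet.cli import main as cli_main
from batfruitnet.report import RunConfig, summary_frame

FAST = RunConfig(
    seed=7,
    n_null_nodf=20,
    n_null_h2=20,
    n_null_mod=3,
    robust_reps=10,
    anneal={"restarts": 1, "proposal_factor": 0.25},
)


@pytest.fixture(scope="module")
def small_analysis():
    m, meta, _, _ = generate_network(GeneratorConfig(n_bats=6, n_plants=8, seed=1))
    return m, meta, analyze_network(m, meta, FAST, network_id="toy")


class TestAnalyzeNetwork:
    def test_all_stages_populated_for_weighted_network(self, small_analysis):
        m, meta, res = small_analysis
        s = res.summary
        assert s.richness == s.n_bats + s.n_plants == 14
        assert 0 <= s.nodf <= 1
        assert 0 <= s.h2_prime <= 1
        assert s.m is not None and s.n_modules >= 1
        assert 0 <= s.r_bats <= 1 and 0 <= s.r_plants <= 1
        assert len(res.roles) == 14
        assert len(res.impacts) == 14
        assert not res.errors

    def test_binary_network_reports_h2_na(self):
        m, meta, _, _ = generate_network(
            GeneratorConfig(n_bats=6, n_plants=8, seed=2, binary=True)
        )
        res = analyze_network(m, meta, FAST)
        assert res.summary.h2_prime is None
        assert "n/a" in res.errors["h2_prime"]
        assert res.summary.nodf is not None  # other stages unaffected

    def test_same_master_seed_identical_summary(self):
        m, meta, _, _ = generate_network(GeneratorConfig(n_bats=6, n_plants=8, seed=3))
        a = analyze_network(m, meta, FAST)
        b = analyze_network(m, meta, FAST)
        assert a.summary == b.summary
        assert np.array_equal(a.robustness_bats.r_values, b.robustness_bats.r_values)


class TestSummarizeSuite:
    def test_field_table_reproduces_reported_means(self):
        """Cross-network means of the published nine-network summary table."""
        suite = summarize_suite(load_field_summaries())
        assert suite.mean("nodf") == pytest.approx(0.56, abs=0.005)
        assert suite.mean("h2_prime") == pytest.approx(0.37, abs=0.005)
        assert suite.n_h2_networks == 8
        assert suite.mean("m") == pytest.approx(0.32, abs=0.005)
        assert round(suite.mean("n_modules")) == 4
        assert suite.mean("r_bats") == pytest.approx(0.55, abs=0.005)
        assert suite.mean("r_plants") == pytest.approx(0.68, abs=0.005)
        assert suite.mean("richness") == pytest.approx(31, abs=0.5)

    def test_field_table_reproduces_reported_sds_and_ranges(self):
        suite = summarize_suite(load_field_summaries())
        assert suite.sd("nodf") == pytest.approx(0.12, abs=0.005)
        assert suite.sd("h2_prime") == pytest.approx(0.10, abs=0.005)
        assert suite.sd("m") == pytest.approx(0.07, abs=0.005)
        assert suite.sd("richness") == pytest.approx(18, abs=0.5)
        assert suite.stats["r_bats"]["min"] == pytest.approx(0.41)
        assert suite.stats["r_bats"]["max"] == pytest.approx(0.69)
        assert suite.stats["r_plants"]["min"] == pytest.approx(0.58)
        assert suite.stats["r_plants"]["max"] == pytest.approx(0.84)

    def test_identical_summaries_zero_sd(self):
        s = NetworkSummary("x", 20, 14, 6, nodf=0.5, m=0.3, n_modules=4)
        suite = summarize_suite([s, s, s])
        assert suite.sd("nodf") == 0.0

    def test_too_few_summaries_rejected(self):
        with pytest.raises(ValueError):
            summarize_suite([NetworkSummary("x", 10, 5, 5)])

    def test_summary_frame_columns(self, small_analysis):
        _, _, res = small_analysis
        df = summary_frame([res.summary])
        assert list(df["network_id"]) == ["toy"]
        assert {"nodf", "h2_prime", "m", "r_bats", "r_plants"} <= set(df.columns)


class TestCli:
    def test_simulate_then_run_pipeline(self, tmp_path):
        runner = CliRunner()
        sim = runner.invoke(
            cli_main,
            ["simulate", "--out", str(tmp_path / "net"), "--seed", "5",
             "--n-bats", "6", "--n-plants", "8"],
        )
        assert sim.exit_code == 0, sim.output
        run = runner.invoke(
            cli_main,
            ["run", "--matrix", str(tmp_path / "net" / "matrix.tsv"),
             "--meta", str(tmp_path / "net" / "metadata.tsv"),
             "--out", str(tmp_path / "res"), "--seed", "1",
             "--nulls-nodf", "10", "--nulls-h2", "10", "--nulls-mod", "2",
             "--robust-reps", "5", "--anneal-restarts", "1"],
        )
        assert run.exit_code == 0, run.output
        assert (tmp_path / "res" / "summary.tsv").exists()
        assert (tmp_path / "res" / "roles.tsv").exists()
        assert (tmp_path / "res" / "manifest.json").exists()

    def test_summarize_field_table(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["summarize", "--field"])
        assert res.exit_code == 0, res.output
        assert "nodf\t0.56" in res.output
        assert "H2' averaged over 8/9" in res.output

    def test_export_edges_command(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("sp,p1,p2\na1,2,0\na2,1,3\n")
        runner = CliRunner()
        res = runner.invoke(
            cli_main, ["export-edges", str(f), "--out", str(tmp_path / "e.tsv")]
        )
        assert res.exit_code == 0, res.output
        assert "wrote 3 edges" in res.output
        assert len((tmp_path / "e.tsv").read_text().splitlines()) == 3

    def test_nestedness_command(self, tmp_path):
        f = tmp_path / "m.csv"
        f.write_text("sp,p1,p2,p3\na1,1,1,1\na2,1,1,0\na3,1,0,0\n")
        runner = CliRunner()
        res = runner.invoke(cli_main, ["nestedness", str(f), "--nulls", "20"])
        assert res.exit_code == 0, res.output
        assert "NODF = 1.0000" in res.output
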