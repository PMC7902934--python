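import json

import numpy as np
import pandas as pd
import pytest

from carpiscan import report
from carpiscan.core_io import GeneTable, PopulationMap, write_vcf
from carpiscan.report import annotate_outliers, overlap_chisq, run_pipeline
from carpiscan.synthgen import bn_genotypes


def yates_chi2(both, a_only, b_only, neither):
    obs = np.array([[both, a_only], [b_only, neither]], float)
    exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    return (((np.abs(obs - exp) - 0.5) ** 2) / exp).sum()


class TestOverlapChisq:
    def test_printed_counts_match_textbook_formula(self):
        table, chi2, p = overlap_chisq(332, 378, total_windows=6616, n_both=66)
        assert chi2 == pytest.approx(yates_chi2(66, 266, 312, 5972), rel=1e-9)
        assert chi2 == pytest.approx(127.4, abs=0.2)
        assert p < 1e-20

    def test_flag_arrays_equivalent_to_counts(self, rng):
        fa = rng.random(5000) < 0.05
        fb = rng.random(5000) < 0.06
        t1, c1, p1 = overlap_chisq(fa, fb)
        t2, c2, p2 = overlap_chisq(int(fa.sum()), int(fb.sum()),
                                   total_windows=5000, n_both=int((fa & fb).sum()))
        assert c1 == pytest.approx(c2) and p1 == pytest.approx(p2)

    def test_null_p_values_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            fa = rng.random(2000) < 0.1
            fb = rng.random(2000) < 0.1
            ps.append(overlap_chisq(fa, fb)[2])
        # no gross excess of small p under the null (4-sigma binomial bound)
        assert np.mean(np.array(ps) < 0.05) <= 0.05 + 4 * np.sqrt(0.05 * 0.95 / 200)

    def test_deficit_detected_two_sided(self):
        # strong avoidance: far fewer joint flags than expected
        _, chi2, p = overlap_chisq(1000, 1000, total_windows=4000, n_both=20)
        assert chi2 > 100 and p < 1e-10

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError):
            overlap_chisq(0, 10, total_windows=100, n_both=0)


class TestAnnotateOutliers:
    def _track(self, flags, starts):
        return pd.DataFrame({
            "contig": "c", "start": starts, "end": [s + 100 for s in starts],
            "value": 1.0, "z": 1.0, "p": 0.5, "outlier": flags,
        })

    def test_no_outliers_header_only(self):
        genes = GeneTable(np.array(["g"]), np.array(["c"]), np.array([0]), np.array([100]))
        out, summary = annotate_outliers(self._track([False, False], [0, 100]), genes)
        assert len(out) == 0
        assert summary == {"n_outlier_windows": 0, "n_distinct_genes": 0}

    def test_shared_gene_counted_once(self):
        genes = GeneTable(np.array(["g"]), np.array(["c"]), np.array([50]), np.array([150]))
        out, summary = annotate_outliers(self._track([True, True], [0, 100]), genes)
        assert summary["n_outlier_windows"] == 2
        assert summary["n_distinct_genes"] == 1
        assert list(out["genes"]) == ["g", "g"]

    def test_counts_match_brute_force_join(self, rng):
        starts = np.arange(50) * 100
        flags = rng.random(50) < 0.3
        gstart = rng.integers(0, 4900, 20)
        genes = GeneTable(np.array([f"g{i}" for i in range(20)]),
                          np.full(20, "c", dtype=object), gstart, gstart + rng.integers(50, 500, 20))
        out, summary = annotate_outliers(self._track(flags, starts), genes)
        expected = set()
        for gid, gs, ge in zip(genes.gene_id, gstart, gstart + (genes.end - genes.start)):
            pass
        expected = {
            str(g)
            for g, gs, ge in zip(genes.gene_id, genes.start, genes.end)
            if any(flags[w] and starts[w] < ge and starts[w] + 100 > gs for w in range(50))
        }
        assert summary["n_distinct_genes"] == len(expected)


class TestRunPipeline:
    def test_end_to_end_on_synthetic_fixture(self, tmp_path, rng):
        table, _ = bn_genotypes(0.2, 2, 6, 3_000, site_spacing=500, seed=12)
        vcf = tmp_path / "in.vcf"
        write_vcf(table, vcf)
        pops = tmp_path / "pops.tsv"
        pops.write_text("".join(f"{s}\t{s.rsplit('_', 1)[0]}\n" for s in table.samples))
        cfg = {
            "vcf": str(vcf), "pops": str(pops),
            "pop_a": "pop1", "pop_b": "pop2",
            "window": 100_000, "alpha": 0.05, "seed": 3,
        }
        out = run_pipeline(cfg, tmp_path / "run")
        manifest = json.loads((out / "manifest.json").read_text())
        assert set(manifest["stages"]) >= {"filter", "diversity", "fst", "struct"}
        fst = pd.read_csv(out / "fst.tsv", sep="\t")
        assert {"value", "z", "p", "outlier"} <= set(fst.columns)
        assert (out / "nj_tree.nwk").read_text().endswith(";\n")

    def test_missing_population_fails_before_compute(self, tmp_path, rng):
        table, _ = bn_genotypes(0.2, 2, 4, 100, seed=1)
        vcf = tmp_path / "in.vcf"
        write_vcf(table, vcf)
        pops = tmp_path / "pops.tsv"
        pops.write_text("".join(f"{s}\t{s.rsplit('_', 1)[0]}\n" for s in table.samples))
        cfg = {"vcf": str(vcf), "pops": str(pops), "pop_a": "nonexistent", "pop_b": "pop2"}
        with pytest.raises(ValueError, match="nonexistent"):
            run_pipeline(cfg, tmp_path / "run")

    def test_rerun_same_seed_identical_outputs(self, tmp_path):
        table, _ = bn_genotypes(0.2, 2, 5, 1_000, site_spacing=500, seed=2)
        vcf = tmp_path / "in.vcf"
        write_vcf(table, vcf)
        pops = tmp_path / "pops.tsv"
        pops.write_text("".join(f"{s}\t{s.rsplit('_', 1)[0]}\n" for s in table.samples))
        cfg = {"vcf": str(vcf), "pops": str(pops), "pop_a": "pop1", "pop_b": "pop2",
               "window": 100_000, "seed": 9}
        out1 = run_pipeline(cfg, tmp_path / "r1")
        out2 = run_pipeline(cfg, tmp_path / "r2")
        assert (out1 / "fst.tsv").read_text() == (out2 / "fst.tsv").read_text()
        assert (out1 / "pi_tajima.tsv").read_text() == (out2 / "pi_tajima.tsv").read_text()


class TestCli:
    def test_overlap_command(self):
        from click.testing import CliRunner

        from carpiscan.cli import main

        res = CliRunner().invoke(main, ["overlap", "--n-both", "66", "--n-a", "332",
                                        "--n-b", "378", "--total", "6616"])
        assert res.exit_code == 0
        assert "chi2=127.4" in res.output

    def test_simulate_and_fst_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from carpiscan.cli import main

        runner = CliRunner()
        prefix = str(tmp_path / "bn")
        res = runner.invoke(main, ["simulate", "bn", "--out-prefix", prefix,
                                   "--seed", "3", "--sites", "2000", "--samples", "8"])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["fst", "--vcf", f"{prefix}.vcf", "--pops", f"{prefix}.pops.tsv",
                                   "--pop-a", "pop1", "--pop-b", "pop2",
                                   "--window", "100000", "--out", str(tmp_path / "fst.tsv")])
        assert res.exit_code == 0, res.output
        assert "genome-wide FST" in res.output
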