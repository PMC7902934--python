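import numpy as np
import pandas as pd
import pytest

from carpiscan.cnv_vst import (
    classify_cnv_genes,
    depth_to_copynumber,
    gene_copynumber,
    vst,
    vst_permutation_test,
)
from carpiscan.core_io import DepthMatrix, GeneTable, PopulationMap, make_windows
from carpiscan.synthgen import simulate_cnv

from _oracles import brute_vst


def _depth_matrix(depth, contig="c", window=10_000, step=10_000):
    depth = np.asarray(depth, dtype=float)
    ws = make_windows({contig: depth.shape[0] * step}, window, step)
    cols = [f"s{i + 1}" for i in range(depth.shape[1])]
    return DepthMatrix(ws, pd.DataFrame(depth, columns=cols))


class TestDepthToCopyNumber:
    def test_uniform_depth_gives_ploidy(self):
        dm = _depth_matrix(np.full((20, 3), 17.0))
        cnm = depth_to_copynumber(dm)
        assert (cnm.cn.to_numpy() == 2).all()

    def test_double_depth_gives_cn4(self):
        d = np.full((20, 1), 10.0)
        d[5] = 20.0
        cnm = depth_to_copynumber(_depth_matrix(d))
        assert cnm.cn.iloc[5, 0] == 4

    def test_zero_median_is_an_error(self):
        with pytest.raises(ValueError, match="median"):
            depth_to_copynumber(_depth_matrix(np.zeros((10, 1))))

    def test_simulation_truth_recovered(self):
        dm, genes, pm, truth = simulate_cnv(100, 0.1, depth_per_copy=15.0, seed=8)
        cnm = depth_to_copynumber(dm)
        agree = (cnm.cn.to_numpy() == truth.params["true_window_cn_int"]).mean()
        assert agree >= 0.95


class TestGeneCopyNumber:
    def test_gene_inside_one_window(self):
        dm = _depth_matrix(np.full((10, 2), 10.0))
        cnm = depth_to_copynumber(dm)
        genes = GeneTable(np.array(["g"]), np.array(["c"]), np.array([20_000]), np.array([30_000]))
        out = gene_copynumber(cnm, genes)
        assert (out.loc["g"] == 2.0).all()

    def test_average_across_windows(self):
        d = np.full((10, 1), 10.0)
        d[3] = 15.0  # CN 3 window
        cnm = depth_to_copynumber(_depth_matrix(d))
        genes = GeneTable(np.array(["g"]), np.array(["c"]), np.array([20_000]), np.array([40_000]))
        out = gene_copynumber(cnm, genes)
        assert out.loc["g"].iloc[0] == pytest.approx(2.5)

    def test_gene_without_windows_missing(self):
        dm = _depth_matrix(np.full((5, 1), 10.0))
        cnm = depth_to_copynumber(dm)
        genes = GeneTable(np.array(["g"]), np.array(["c"]), np.array([90_000]), np.array([95_000]))
        assert gene_copynumber(cnm, genes).loc["g"].isna().all()

    def test_random_layout_matches_brute_force(self, rng):
        d = rng.uniform(5, 25, (50, 3))
        cnm = depth_to_copynumber(_depth_matrix(d, step=2_000, window=10_000))
        starts = rng.integers(0, 80_000, 20)
        genes = GeneTable(np.array([f"g{i}" for i in range(20)]),
                          np.full(20, "c", dtype=object), starts, starts + rng.integers(1_000, 30_000, 20))
        out = gene_copynumber(cnm, genes)
        ws = cnm.windows
        for gi, (gid, gs, ge) in enumerate(zip(genes.gene_id, genes.start, genes.end)):
            hits = [w for w in range(len(ws)) if ws.start[w] < ge and ws.end[w] > gs]
            expected = cnm.cn.to_numpy()[hits].mean(axis=0) if hits else np.full(3, np.nan)
            np.testing.assert_allclose(out.loc[gid].to_numpy(), expected)


class TestVst:
    def test_full_separation(self):
        v = vst(np.array([2, 2, 2, 4, 4, 4], float), np.arange(3), np.arange(3, 6))
        assert v == pytest.approx(1.0)

    def test_identical_distributions_zero(self):
        v = vst(np.array([2, 3, 2, 3], float), np.array([0, 1]), np.array([2, 3]))
        assert v == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # pop1 = [2,2], pop2 = [2,4]: V_T = 0.75, V_S = 0.5, V_ST = 1/3
        v = vst(np.array([2, 2, 2, 4], float), np.array([0, 1]), np.array([2, 3]))
        assert v == pytest.approx(1.0 / 3.0)

    def test_constant_gene_missing(self):
        assert np.isnan(vst(np.full(6, 2.0), np.arange(3), np.arange(3, 6)))

    def test_symmetry_and_shift_invariance(self, rng):
        vals = rng.normal(3, 1, 12)
        a, b = np.arange(5), np.arange(5, 12)
        assert vst(vals, a, b) == pytest.approx(vst(vals, b, a))
        assert vst(vals + 7.0, a, b) == pytest.approx(vst(vals, a, b))

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            vals = rng.normal(2, 0.8, 15)
            got = vst(vals, np.arange(8), np.arange(8, 15))
            assert got == pytest.approx(brute_vst(vals, range(8), range(8, 15)), rel=1e-12)


class TestVstPermutation:
    def _gene_cn(self, rows, samples):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))], columns=samples)

    def _popmap(self, na, nb):
        samples = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
        return samples, PopulationMap({s: ("A" if s.startswith("a") else "B") for s in samples})

    def test_fully_separated_gene_flagged_any_seed(self):
        samples, pm = self._popmap(6, 6)
        gcn = self._gene_cn([[2] * 6 + [4] * 6], samples)
        for seed in (0, 1, 99):
            res = vst_permutation_test(gcn, pm, "A", "B", n_perm=500, seed=seed)
            assert bool(res.table["significant"].iloc[0])

    def test_constant_gene_not_flagged(self):
        samples, pm = self._popmap(5, 5)
        gcn = self._gene_cn([[2.0] * 10], samples)
        res = vst_permutation_test(gcn, pm, "A", "B", n_perm=200, seed=0)
        assert not bool(res.table["significant"].iloc[0])
        assert np.isnan(res.table["vst"].iloc[0])

    def test_seed_reproducibility(self, rng):
        samples, pm = self._popmap(8, 6)
        gcn = self._gene_cn(rng.normal(2, 0.5, (30, 14)), samples)
        r1 = vst_permutation_test(gcn, pm, "A", "B", n_perm=300, seed=5)
        r2 = vst_permutation_test(gcn, pm, "A", "B", n_perm=300, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_threshold_monotone_in_quantile(self, rng):
        samples, pm = self._popmap(8, 6)
        gcn = self._gene_cn(rng.normal(2, 0.5, (10, 14)), samples)
        t90 = vst_permutation_test(gcn, pm, "A", "B", n_perm=400, quantile=0.90, seed=3)
        t99 = vst_permutation_test(gcn, pm, "A", "B", n_perm=400, quantile=0.99, seed=3)
        assert (t99.table["threshold"] >= t90.table["threshold"] - 1e-12).all()

    def test_low_perm_count_warns(self, rng):
        samples, pm = self._popmap(4, 4)
        gcn = self._gene_cn(rng.normal(2, 0.5, (3, 8)), samples)
        with pytest.warns(UserWarning, match="coarse"):
            vst_permutation_test(gcn, pm, "A", "B", n_perm=50, seed=0)


class TestClassifyCnvGenes:
    def test_baseline_genome_has_no_cnv_genes(self):
        samples = ["a1", "a2", "b1"]
        pm = PopulationMap({"a1": "A", "a2": "A", "b1": "B"})
        gcn = pd.DataFrame(np.full((5, 3), 2.0), columns=samples)
        out = classify_cnv_genes(gcn, pm)
        assert (out["mean_duplicated"] == 0).all() and (out["mean_absent"] == 0).all()

    def test_absent_gene_counted_per_population(self):
        samples = ["a1", "a2", "b1", "b2"]
        pm = PopulationMap({s: s[0].upper() for s in samples})
        cn = np.full((4, 4), 2.0)
        cn[0, 0] = 0.0  # one absent gene in one A sample
        cn[1, 3] = 5.0  # one duplicated gene in one B sample
        out = classify_cnv_genes(pd.DataFrame(cn, columns=samples), pm)
        assert out.loc["A", "mean_absent"] == pytest.approx(0.5)
        assert out.loc["B", "mean_duplicated"] == pytest.approx(0.5)

    def test_matches_enumeration(self, rng):
        samples = [f"s{i}" for i in range(6)]
        pm = PopulationMap({s: ("A" if i < 3 else "B") for i, s in enumerate(samples)})
        cn = rng.integers(0, 6, (40, 6)).astype(float)
        out = classify_cnv_genes(pd.DataFrame(cn, columns=samples), pm)
        rounded = np.rint(cn)
        for pop, cols in (("A", [0, 1, 2]), ("B", [3, 4, 5])):
            dup = np.mean([(rounded[:, c] >= 3).sum() for c in cols])
            absent = np.mean([(rounded[:, c] == 0).sum() for c in cols])
            assert out.loc[pop, "mean_duplicated"] == pytest.approx(dup)
            assert out.loc[pop, "mean_absent"] == pytest.approx(absent)
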