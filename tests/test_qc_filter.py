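import numpy as np
import pytest

from carpiscan import qc_filter
from carpiscan.qc_filter import (
    SNP_HARD_CLAUSES,
    hard_filter_indels,
    hard_filter_snps,
    ibs_matrix,
    indel_proximity_filter,
    prune_related,
    site_level_filter,
)
from carpiscan.synthgen import annotate_info_fields, bn_genotypes

from _oracles import brute_ibs
from conftest import build_table, random_table


def _info_table(rng, n=1, **info):
    g = np.zeros((n, 2, 2), dtype=np.int8)
    return build_table(g, info={k: np.full(n, v) for k, v in info.items()})


class TestHardFilters:
    def test_low_qd_snp_removed(self, rng):
        table = _info_table(rng, QD=1.9)
        kept, rep = hard_filter_snps(table)
        assert kept.n_sites == 0
        assert rep.removed_by["QD"] == 1

    def test_boundary_values_pass(self, rng):
        # strict inequalities: sites sitting exactly on a threshold survive
        table = _info_table(rng, QD=2.0, FS=60.0, ReadPosRankSum=-8.0,
                            MQ=40.0, MQRankSum=-12.5, SOR=3.0)
        kept, _ = hard_filter_snps(table)
        assert kept.n_sites == 1

    def test_missing_annotations_tolerated(self, rng):
        table = _info_table(rng, FS=10.0)  # no QD etc
        kept, _ = hard_filter_snps(table)
        assert kept.n_sites == 1

    def test_indel_thresholds(self, rng):
        bad = _info_table(rng, FS=250.0)
        kept, rep = hard_filter_indels(bad)
        assert kept.n_sites == 0 and rep.removed_by["FS"] == 1
        ok = _info_table(rng)  # unannotated indel survives
        assert hard_filter_indels(ok)[0].n_sites == 1

    def test_synthetic_annotations_match_construction_truth(self):
        table, _ = bn_genotypes(0.1, 2, 4, 1000, seed=5)
        annotated, truth = annotate_info_fields(table, clean_fraction=0.7, seed=9)
        kept, _ = hard_filter_snps(annotated)
        assert kept.n_sites == truth.params["n_expected_survivors"]
        # every clause is exercised at least once per 1,000 sites
        clauses = set(truth.params["failing_clause"]) - {""}
        assert clauses == {k for k, _, _ in SNP_HARD_CLAUSES}

    def test_random_sites_match_per_clause_oracle(self, rng):
        n = 500
        info = {
            "QD": rng.uniform(0, 10, n),
            "FS": rng.uniform(0, 100, n),
            "ReadPosRankSum": rng.uniform(-12, 4, n),
            "MQ": rng.uniform(30, 60, n),
            "MQRankSum": rng.uniform(-16, 4, n),
            "SOR": rng.uniform(0, 5, n),
        }
        table = build_table(np.zeros((n, 2, 2), dtype=np.int8), info=info)
        kept, _ = hard_filter_snps(table)
        survive = [
            i for i in range(n)
            if not (info["QD"][i] < 2.0 or info["FS"][i] > 60.0
                    or info["ReadPosRankSum"][i] < -8.0 or info["MQ"][i] < 40.0
                    or info["MQRankSum"][i] < -12.5 or info["SOR"][i] > 3.0)
        ]
        assert kept.n_sites == len(survive)
        np.testing.assert_array_equal(kept.pos, table.pos[survive])


class TestSiteLevelFilter:
    def test_qual_boundary(self, rng):
        g = np.zeros((2, 2, 2), dtype=np.int8)
        table = build_table(g, qual=[49.9, 50.0], info={"DP": [30, 30]})
        kept, rep = site_level_filter(table)
        assert kept.n_sites == 1 and rep.removed_by["qual"] == 1

    def test_depth_clauses(self, rng):
        # mean depth 30: >90 and <10 removed
        dp = [30.0] * 8 + [120.0, 5.0]
        g = np.zeros((10, 2, 2), dtype=np.int8)
        table = build_table(g, qual=[60] * 10, info={"DP": dp})
        kept, rep = site_level_filter(table)
        assert rep.removed_by["depth"] == 2
        assert kept.n_sites == 8

    def test_triallelic_removed(self, rng):
        g = np.array([[[0, 1], [1, 2]], [[0, 1], [0, 0]]], dtype=np.int8)
        table = build_table(g, qual=[60, 60], info={"DP": [30, 30]}, alt=("T", "G"))
        kept, rep = site_level_filter(table)
        assert kept.n_sites == 1 and rep.removed_by["multiallelic"] == 1

    def test_missing_depth_is_an_error(self, rng):
        table = build_table(np.zeros((1, 2, 2), dtype=np.int8), qual=[60])
        with pytest.raises(ValueError, match="depth"):
            site_level_filter(table)

    def test_crafted_ten_records_six_survive(self):
        # 4 records each fail exactly one clause; 6 survive
        g = np.zeros((10, 2, 2), dtype=np.int8)
        g[7] = [[0, 1], [1, 2]]  # triallelic
        qual = [60, 60, 60, 49, 60, 60, 60, 60, 60, 60]
        dp = [30, 30, 30, 30, 150, 8, 30, 30, 30, 30]
        table = build_table(g, qual=qual, info={"DP": dp}, alt=("T", "G"))
        kept, _ = site_level_filter(table)
        assert kept.n_sites == 6
        assert set(kept.pos) == set(table.pos[[0, 1, 2, 6, 8, 9]])


class TestIndelProximity:
    @pytest.mark.parametrize("offset,kept_expected", [(5, 0), (6, 1)])
    def test_distance_boundary(self, offset, kept_expected):
        snps = build_table(np.zeros((1, 1, 2), dtype=np.int8), positions=[1000 + offset])
        indels = build_table(np.zeros((1, 1, 2), dtype=np.int8), positions=[1000], vclass="indel")
        kept, _ = indel_proximity_filter(snps, indels, radius=5)
        assert kept.n_sites == kept_expected

    def test_random_placements_match_all_pairs(self, rng):
        spos = np.sort(rng.choice(10_000, 300, replace=False))
        ipos = np.sort(rng.choice(10_000, 40, replace=False))
        snps = build_table(np.zeros((300, 1, 2), dtype=np.int8), positions=spos)
        indels = build_table(np.zeros((40, 1, 2), dtype=np.int8), positions=ipos, vclass="indel")
        kept, _ = indel_proximity_filter(snps, indels, radius=5)
        expected = [p for p in spos if all(abs(p - q) > 5 for q in ipos)]
        assert list(kept.pos) == expected

    def test_other_contig_not_affected(self):
        snps = build_table(np.zeros((1, 1, 2), dtype=np.int8), positions=[1000], contig="chr2")
        indels = build_table(np.zeros((1, 1, 2), dtype=np.int8), positions=[1000], contig="chr1", vclass="indel")
        kept, _ = indel_proximity_filter(snps, indels)
        assert kept.n_sites == 1


class TestIbs:
    def test_identical_and_opposite(self):
        g = np.zeros((10, 2, 2), dtype=np.int8)
        m = ibs_matrix(build_table(g))
        assert m[0, 1] == 1.0
        g2 = np.zeros((10, 2, 2), dtype=np.int8)
        g2[:, 1] = 1  # 0/0 vs 1/1
        assert ibs_matrix(build_table(g2))[0, 1] == 0.0
        g3 = np.zeros((10, 2, 2), dtype=np.int8)
        g3[:, 1, 1] = 1  # 0/0 vs 0/1
        assert ibs_matrix(build_table(g3))[0, 1] == 0.5

    def test_random_matches_pairwise_oracle(self, rng):
        table = random_table(rng, n_sites=300, n_samples=6, missing_rate=0.1)
        m = ibs_matrix(table)
        for i in range(6):
            for j in range(i + 1, 6):
                assert m[i, j] == pytest.approx(brute_ibs(table.genotypes, i, j))

    def test_pair_without_shared_sites_is_missing(self):
        g = np.full((4, 2, 2), -1, dtype=np.int8)
        g[:2, 0] = 0
        g[2:, 1] = 0
        m = ibs_matrix(build_table(g))
        assert np.isnan(m[0, 1])


class TestPruneRelated:
    def test_single_close_pair_drops_one(self):
        m = np.array([[1.0, 0.95, 0.2], [0.95, 1.0, 0.3], [0.2, 0.3, 1.0]])
        kept, dropped = prune_related(m, ["a", "b", "c"], threshold=0.9)
        assert len(dropped) == 1 and dropped[0] in {"a", "b"}
        assert len(kept) == 2

    def test_no_pair_above_threshold(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        kept, dropped = prune_related(m, ["a", "b", "c"])
        assert dropped == [] and kept == ["a", "b", "c"]

    def test_duplicate_triplet_drops_two(self):
        m = np.full((4, 4), 0.4)
        for i in (0, 1, 2):
            for j in (0, 1, 2):
                m[i, j] = 0.97
        np.fill_diagonal(m, 1.0)
        kept, dropped = prune_related(m, list("abcd"))
        assert len(dropped) == 2 and "d" in kept
        # stopping condition: no surviving pair above threshold
        idx = [list("abcd").index(s) for s in kept]
        for x in idx:
            for y in idx:
                assert x == y or m[x, y] <= 0.9


class TestCascadeProperties:
    def test_idempotence(self, rng):
        table, _ = annotate_info_fields(random_table(rng, 300, 4), clean_fraction=0.6, seed=1)
        once, rep1 = hard_filter_snps(table)
        twice, rep2 = hard_filter_snps(once)
        assert twice.n_sites == once.n_sites
        assert rep2.n_removed == 0

    def test_report_counts_consistent(self, rng):
        table, _ = annotate_info_fields(random_table(rng, 500, 4), clean_fraction=0.5, seed=2)
        kept, rep = hard_filter_snps(table)
        assert rep.n_in - rep.n_out == table.n_sites - kept.n_sites
        assert rep.n_removed <= sum(rep.removed_by.values())
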