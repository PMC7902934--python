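import numpy as np
import pytest
from scipy.stats import kstest

from carpiscan.core_io import PopulationMap
from carpiscan.divergence import genome_fst
from carpiscan.synthgen import (
    DemographyConfig,
    PulseEvent,
    SweepConfig,
    annotate_info_fields,
    bn_genotypes,
    carpinus_preset,
    neutral_preset,
    quartet_preset,
    rescaled,
    simulate_cnv,
    sweep_preset,
    wf_simulate,
)


def popmap_for(table, outgroups=()):
    return PopulationMap({s: s.rsplit("_", 1)[0] for s in table.samples}, outgroups)


class TestBnGenotypes:
    def test_deterministic_under_seed(self):
        t1, _ = bn_genotypes(0.1, 2, 5, 200, seed=9)
        t2, _ = bn_genotypes(0.1, 2, 5, 200, seed=9)
        np.testing.assert_array_equal(t1.genotypes, t2.genotypes)

    def test_no_differentiation_limit(self):
        table, _ = bn_genotypes(0.001, 2, 20, 10_000, seed=1)
        fst = genome_fst(table, popmap_for(table), "pop1", "pop2")
        assert abs(fst) < 0.01

    def test_frequencies_follow_beta_marginal(self):
        F, n_sites = 0.2, 4_000
        _, truth = bn_genotypes(F, 1, 5, n_sites, maf_floor=0.5 - 1e-9, seed=3)
        # with the ancestral frequency pinned at 0.5 the marginal is a
        # single Beta(a, a) with a = 0.5 (1 - F) / F
        freq = truth.params["population_freq"][:, 0]
        a = 0.5 * (1 - F) / F
        assert kstest(freq, "beta", args=(a, a)).pvalue > 0.01

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            bn_genotypes(0.0, 2, 5, 10)


class TestWfUnlinked:
    def test_mu_zero_is_monomorphic(self):
        cfg = DemographyConfig(sizes=(20,), split_times=(0,), parents=(0,),
                               n_anc=20, mu=0.0, L=500, sample_sizes=(5,))
        table, _ = wf_simulate(cfg, seed=1)
        assert table.n_sites == 0  # nothing segregates

    def test_deterministic_under_seed(self):
        cfg = neutral_preset(n_sites=2_000)
        t1, _ = wf_simulate(cfg, seed=4)
        t2, _ = wf_simulate(cfg, seed=4)
        np.testing.assert_array_equal(t1.genotypes, t2.genotypes)
        np.testing.assert_array_equal(t1.pos, t2.pos)

    def test_no_split_twin_labels_fst_near_zero(self):
        # one panmictic population sampled twice under two labels
        cfg = DemographyConfig(sizes=(50,), split_times=(0,), parents=(0,),
                               n_anc=50, mu=3e-5, L=20_000, sample_sizes=(20,))
        table, _ = wf_simulate(cfg, seed=6)
        labels = {s: ("popX" if i < 10 else "popY") for i, s in enumerate(table.samples)}
        pm = PopulationMap(labels)
        assert abs(genome_fst(table, pm, "popX", "popY")) < 0.02

    def test_expected_diversity_scale(self):
        cfg = neutral_preset(n_sites=50_000)
        table, _ = wf_simulate(cfg, seed=8)
        # E[S] = theta * a1(n-1) * L with theta = 0.006, n = 20
        a1 = np.sum(1.0 / np.arange(1, 20))
        expected = 0.006 * a1 * 50_000
        assert table.n_sites == pytest.approx(expected, rel=0.25)

    def test_migration_limits_differentiation(self):
        base = dict(sizes=(50, 50), split_times=(0, 100), parents=(0, 0), n_anc=50,
                    mu=3e-5, L=20_000, sample_sizes=(15, 15))
        isolated, _ = wf_simulate(DemographyConfig(**base), seed=11)
        mixed, _ = wf_simulate(DemographyConfig(**base, migration={(0, 1): 0.2, (1, 0): 0.2}), seed=11)
        f_iso = genome_fst(isolated, popmap_for(isolated), "pop1", "pop2")
        f_mix = genome_fst(mixed, popmap_for(mixed), "pop1", "pop2")
        assert f_mix < f_iso

    def test_rescaling_preserves_diversity(self):
        # same theta at two scales -> same expected segregating-site count
        big = DemographyConfig(sizes=(100,), split_times=(0,), parents=(0,),
                               n_anc=100, mu=1.5e-5, L=30_000, sample_sizes=(10,))
        small = rescaled(big, 2.0)
        assert small.n_anc == 50 and small.mu == pytest.approx(3e-5)
        s_big = wf_simulate(big, seed=13)[0].n_sites
        s_small = wf_simulate(small, seed=14)[0].n_sites
        assert s_small == pytest.approx(s_big, rel=0.2)


class TestWfLinked:
    def test_phased_output_and_determinism(self):
        cfg = sweep_preset(with_sweep=False, n_sites=2_000, n=50)
        t1, _ = wf_simulate(cfg, seed=3, engine="linked")
        t2, _ = wf_simulate(cfg, seed=3, engine="linked")
        assert t1.phased.all()
        np.testing.assert_array_equal(t1.genotypes, t2.genotypes)

    def test_sweep_reaches_conditioned_frequency(self):
        cfg = sweep_preset(n_sites=2_000, n=50)
        table, truth = wf_simulate(cfg, seed=5, engine="linked")
        assert truth.params["sweep_end_freq"] >= cfg.sweep.min_end_freq
        assert truth.params["sweep_position"] == cfg.sweep.site_index * cfg.site_spacing

    def test_diversity_matches_count_engine(self):
        # the two engines share the model: segregating-site counts agree
        base = dict(sizes=(50,), split_times=(0,), parents=(0,), n_anc=50,
                    mu=3e-5, L=20_000, site_spacing=100, sample_sizes=(10,))
        s_unlinked = wf_simulate(DemographyConfig(**base), seed=21)[0].n_sites
        s_linked = wf_simulate(DemographyConfig(**base, r=1e-6), seed=22, engine="linked")[0].n_sites
        assert s_linked == pytest.approx(s_unlinked, rel=0.25)


class TestAnnotateInfoFields:
    def test_clean_fraction_one_no_failures(self, rng):
        table, truth = annotate_info_fields(bn_genotypes(0.1, 1, 4, 300, seed=1)[0], 1.0, seed=2)
        assert truth.params["n_expected_survivors"] == 300

    def test_construction_truth_exact(self):
        table, truth = annotate_info_fields(bn_genotypes(0.1, 1, 4, 100, seed=1)[0], 0.7, seed=3)
        expected = truth.params["expected_pass"]
        assert truth.params["n_expected_survivors"] == int(expected.sum())
        fails = truth.params["failing_clause"][~expected]
        assert all(c != "" for c in fails)


class TestSimulateCnv:
    def test_noiseless_limit_recovers_cn_exactly(self):
        dm, genes, pm, truth = simulate_cnv(50, 0.1, noise_sd=0.0, depth_per_copy=400.0, seed=5)
        from carpiscan.cnv_vst import depth_to_copynumber

        cnm = depth_to_copynumber(dm)
        assert (cnm.cn.to_numpy() == truth.params["true_window_cn_int"]).all()

    def test_deterministic_under_seed(self):
        d1 = simulate_cnv(20, 0.1, seed=9)[0].depth
        d2 = simulate_cnv(20, 0.1, seed=9)[0].depth
        np.testing.assert_array_equal(d1.to_numpy(), d2.to_numpy())

    def test_differentiated_genes_have_high_vst(self):
        from carpiscan.cnv_vst import depth_to_copynumber, gene_copynumber, vst

        dm, genes, pm, truth = simulate_cnv(60, 0.2, pop_means=(2, 4), noise_sd=0.3, seed=6)
        gcn = gene_copynumber(depth_to_copynumber(dm), genes)
        samples = list(gcn.columns)
        ia = pm.indices_of("popA", samples)
        ib = pm.indices_of("popB", samples)
        diff = truth.params["differentiated"]
        vals = np.array([vst(gcn.iloc[g].to_numpy(), ia, ib) for g in range(60)])
        assert np.nanmean(vals[diff]) > 0.8
        assert np.nanmean(np.abs(vals[~diff])) < 0.2


class TestPresets:
    def test_carpinus_preset_anchors(self):
        cfg = carpinus_preset()
        assert cfg.split_times[1] == 80_000
        assert cfg.mu == pytest.approx(5.625e-7)
        # theta = 4 N mu ~ the study's per-site diversity
        assert 4 * cfg.n_anc * cfg.mu == pytest.approx(0.005625)

    def test_rescaled_preserves_compound_parameters(self):
        cfg = carpinus_preset()
        small = rescaled(cfg, 50.0)
        assert 4 * small.n_anc * small.mu == pytest.approx(4 * cfg.n_anc * cfg.mu, rel=1e-6)
        assert small.split_times[1] / small.n_anc == pytest.approx(
            cfg.split_times[1] / cfg.n_anc, rel=0.05)

    def test_quartet_preset_shape(self):
        cfg = quartet_preset(0.3)
        assert cfg.n_pops == 4
        assert cfg.pulse.fraction == 0.3
        assert cfg.pulse.donor == 2 and cfg.pulse.recipient == 1
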