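"""Unit and property tests for the forward simulator."""

import numpy as np
import pandas as pd
import pytest

from methylaxis.simulate import (
    GROUPS,
    SPIKE_HMC,
    SPIKE_METH,
    SPIKE_UNMETH,
    SimConfig,
    SimulationError,
    cytosine_catalog,
    simulate_bs_counts,
    simulate_dataset,
    simulate_expression,
    simulate_genome,
    simulate_methylome,
    simulate_spikeins,
    simulate_tab_counts,
    tab_unconverted_fraction,
)


class TestCatalog:
    def test_palindromic_cg_both_strands(self):
        cat = cytosine_catalog({"chr1": "ACGT"})
        plus = cat[cat["strand"] == "+"]
        minus = cat[cat["strand"] == "-"]
        assert plus["pos"].tolist() == [2]
        assert plus["context_class"].tolist() == ["CG"]
        assert minus["pos"].tolist() == [3]
        assert minus["context_class"].tolist() == ["CG"]
        # minus-strand context reads from the reverse complement
        assert minus["context"].tolist() == ["CGT"]

    def test_ch_context_read_off(self):
        cat = cytosine_catalog({"chr1": "ACAT"})
        assert len(cat) == 1
        row = cat.iloc[0]
        assert (row["pos"], row["strand"], str(row["context_class"])) == (2, "+", "CA")
        assert row["context"] == "CAT"

    def test_every_catalogued_cytosine_in_one_class(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 2_000))
        cat = cytosine_catalog({"chr1": seq})
        assert cat["context_class"].isin(["CG", "CA", "CC", "CT"]).all()
        # one record per (pos, strand)
        assert not cat.duplicated(["chrom", "pos", "strand"]).any()
        # every internal C appears
        n_c_internal = sum(1 for i in range(len(seq) - 1) if seq[i] == "C")
        assert (cat["strand"] == "+").sum() == n_c_internal

    def test_same_seed_identical_catalog(self):
        cfg = SimConfig(genome_size=10_000, n_chromosomes=1, n_genes=2, n_de_genes=1, n_dmrs=2)
        _, cat1 = simulate_genome(cfg)
        _, cat2 = simulate_genome(cfg)
        pd.testing.assert_frame_equal(cat1, cat2)

    def test_sizing_error(self):
        cfg = SimConfig(genome_size=5_000, n_chromosomes=1, n_dmrs=50, dmr_length_bp=1_000)
        with pytest.raises(SimulationError, match="too small"):
            cfg.validate()


@pytest.fixture(scope="module")
def catalog_20kb():
    cfg = SimConfig(genome_size=20_000, n_chromosomes=1, n_genes=2, n_de_genes=1, n_dmrs=2)
    return cfg, simulate_genome(cfg)[1]


class TestMethylome:
    def test_zero_mean_diff_gives_identical_group_means(self, catalog_20kb):
        cfg, cat = catalog_20kb
        cfg = SimConfig(**{**cfg.__dict__, "dmr_mean_diff": 0.0})
        state, truth = simulate_methylome(cat, cfg, np.random.default_rng(0))
        d = state["dorsal_SH"]["p_mc_only"] + state["dorsal_SH"]["p_hmc"]
        v = state["ventral_SH"]["p_mc_only"] + state["ventral_SH"]["p_hmc"]
        cg = cat["context_class"] == "CG"
        assert np.allclose(d[cg], v[cg])  # exactly identical CG levels
        assert (truth["delta"] == 0).all()

    def test_hmc_only_at_cg(self, catalog_20kb):
        cfg, cat = catalog_20kb
        state, _ = simulate_methylome(cat, cfg, np.random.default_rng(1))
        ch = cat["context_class"] != "CG"
        for g in GROUPS:
            assert (state[g].loc[ch.to_numpy(), "p_hmc"] == 0).all()

    def test_state_in_simplex(self, catalog_20kb):
        cfg, cat = catalog_20kb
        state, _ = simulate_methylome(cat, cfg, np.random.default_rng(2))
        for g in GROUPS:
            tot = state[g]["p_mc_only"] + state[g]["p_hmc"]
            assert (state[g]["p_mc_only"] >= 0).all()
            assert (state[g]["p_hmc"] >= 0).all()
            assert (tot <= 1 + 1e-12).all()

    def test_mch_ratio_converges_to_config(self):
        # ~35k CH sites: pooled ventral/dorsal CH ratio within 3 s.e. of 2
        cfg = SimConfig(
            genome_size=100_000, n_chromosomes=1, n_genes=4, n_de_genes=1,
            n_dmrs=2, ncr_true=0.0, coverage_mean=20, seed=5,
        )
        _, cat = simulate_genome(cfg)
        cat = cat[cat["context_class"].isin(["CA", "CC", "CT"])].reset_index(drop=True)
        state, _ = simulate_methylome(cat, cfg, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        lev = {}
        se2 = {}
        for g in ("dorsal_SH", "ventral_SH"):
            t = simulate_bs_counts(cat, state[g], cfg, rng)
            m, c = t["mc_count"].sum(), t["total_count"].sum()
            lev[g] = m / c
            se2[g] = lev[g] * (1 - lev[g]) / c
        ratio = lev["ventral_SH"] / lev["dorsal_SH"]
        se_ratio = ratio * np.sqrt(
            se2["ventral_SH"] / lev["ventral_SH"] ** 2
            + se2["dorsal_SH"] / lev["dorsal_SH"] ** 2
        )
        assert abs(ratio - 2.0) < 3 * se_ratio

    def test_clipped_truth_flag(self, catalog_20kb):
        cfg, cat = catalog_20kb
        cfg = SimConfig(**{**cfg.__dict__, "baseline_mcg": 0.2, "dmr_mean_diff": 0.5})
        _, truth = simulate_methylome(cat, cfg, np.random.default_rng(3))
        assert truth["clipped"].any()


class TestAssayCounts:
    def _state(self, cat, p_mc_only, p_hmc):
        return pd.DataFrame(
            {"p_mc_only": np.full(len(cat), p_mc_only), "p_hmc": np.full(len(cat), p_hmc)},
            index=cat.index,
        )

    def test_bs_extremes(self, catalog_20kb):
        cfg, cat = catalog_20kb
        cfg = SimConfig(**{**cfg.__dict__, "ncr_true": 0.0})
        rng = np.random.default_rng(0)
        full = simulate_bs_counts(cat, self._state(cat, 1.0, 0.0), cfg, rng)
        assert (full["mc_count"] == full["total_count"]).all()
        empty = simulate_bs_counts(cat, self._state(cat, 0.0, 0.0), cfg, rng)
        assert (empty["mc_count"] == 0).all()
        assert (empty["total_count"] >= 1).all()  # truncated coverage

    def test_bs_pooled_expectation(self):
        cfg = SimConfig(
            genome_size=150_000, n_chromosomes=1, n_genes=4, n_de_genes=1,
            n_dmrs=2, ncr_true=0.01, coverage_mean=20,
        )
        _, cat = simulate_genome(cfg)
        cat = cat.head(100_000)
        state = self._state(cat, 0.5, 0.0)
        t = simulate_bs_counts(cat, state, cfg, np.random.default_rng(1))
        m, c = t["mc_count"].sum(), t["total_count"].sum()
        expected = 0.5 + 0.5 * 0.01
        se = np.sqrt(expected * (1 - expected) / c)
        assert abs(m / c - expected) < 3 * se

    def test_tab_forward_model_hand_value(self):
        q = tab_unconverted_fraction(0.2, 0.7, r=0.01, s=0.03, t=0.1)
        assert q == pytest.approx(0.204, abs=1e-12)
        assert tab_unconverted_fraction(1.0, 1.0, 0, 0, 0) == 1.0
        assert tab_unconverted_fraction(0.0, 0.0, 0, 0, 0) == 0.0

    def test_tab_out_of_range_is_model_misuse(self, catalog_20kb):
        cfg, cat = catalog_20kb
        cfg = SimConfig(**{**cfg.__dict__, "t_true": 0.0, "s_true": 0.5})
        state = self._state(cat, 0.0, 1.0)  # q = 1 + s > 1
        with pytest.raises(SimulationError, match="outside"):
            simulate_tab_counts(cat, state, cfg, np.random.default_rng(0))


class TestSpikeins:
    def test_unmethylated_contig_clean_without_ncr(self):
        cfg = SimConfig(ncr_true=0.0, r_true=0.0, spikein_length=2_000)
        sp = simulate_spikeins(cfg, np.random.default_rng(0))
        un_bs = sp[(sp["chrom"] == SPIKE_UNMETH) & (sp["assay"] == "BS")]
        assert un_bs["mc_count"].sum() == 0

    def test_pure_protected_hmc_contig_fully_methylated_in_bs(self):
        # s = r = 0 keeps the TAB forward model inside [0, 1] at purity 1
        cfg = SimConfig(
            hmc_spike_purity=1.0, t_true=0.0, ncr_true=0.0,
            s_true=0.0, r_true=0.0, spikein_length=2_000,
        )
        sp = simulate_spikeins(cfg, np.random.default_rng(1))
        c_bs = sp[(sp["chrom"] == SPIKE_HMC) & (sp["assay"] == "BS")]
        from methylaxis.simulate import context_class

        cg = context_class(c_bs["context"]) == "CG"
        assert (c_bs.loc[cg, "mc_count"] == c_bs.loc[cg, "total_count"]).all()

    def test_methylated_contig_tab_rate_matches_s(self):
        cfg = SimConfig(s_true=0.05, spikein_length=6_000, spikein_coverage=30)
        sp = simulate_spikeins(cfg, np.random.default_rng(2))
        from methylaxis.simulate import context_class

        b = sp[(sp["chrom"] == SPIKE_METH) & (sp["assay"] == "TAB")]
        b = b[context_class(b["context"]) == "CG"]
        m, c = b["mc_count"].sum(), b["total_count"].sum()
        assert c > 10_000
        se = np.sqrt(0.05 * 0.95 / c)
        assert abs(m / c - 0.05) < 3 * se


class TestExpression:
    def test_zero_fold_change_means_no_true_de(self):
        cfg = SimConfig(de_log2fc=0.0, n_genes=50, n_de_genes=5)
        _, _, truth, _ = simulate_expression(cfg)
        assert (truth["log2fc"] == 0).all()

    def test_low_dispersion_limit_recovers_fold_change(self):
        cfg = SimConfig(
            n_genes=400, n_de_genes=400, de_log2fc=1.0, nb_dispersion=1e-12,
            expr_mean=2_000, expr_sigma=0.0, library_size_sd=0.0, n_replicates=10,
        )
        counts, samples, truth, _ = simulate_expression(cfg)
        cell = samples["region"] + "_" + samples["condition"]
        up = truth.loc[truth["log2fc"] > 0, "gene"]
        ratio = (
            counts.loc[up, samples.index[cell == "dorsal_EE"]].mean(axis=1)
            / counts.loc[up, samples.index[cell == "dorsal_SH"]].mean(axis=1)
        )
        assert np.allclose(ratio, 2.0, rtol=0.05)

    def test_seeded_run_reproducible(self):
        cfg = SimConfig(n_genes=100, n_de_genes=10, seed=3)
        c1, s1, t1, _ = simulate_expression(cfg)
        c2, s2, t2, _ = simulate_expression(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_contaminated_sample_recorded(self):
        cfg = SimConfig(n_genes=50, n_de_genes=5, xist_contamination=True)
        counts, _, _, contaminated = simulate_expression(cfg)
        assert contaminated is not None
        assert "Xist" in counts.index


class TestDatasetDeterminism:
    def test_identical_config_identical_outputs(self, small_config, small_dataset):
        ds2 = simulate_dataset(small_config)
        pd.testing.assert_frame_equal(small_dataset.catalog, ds2.catalog)
        pd.testing.assert_frame_equal(small_dataset.spikeins, ds2.spikeins)
        pd.testing.assert_frame_equal(small_dataset.counts, ds2.counts)
        pd.testing.assert_frame_equal(small_dataset.truth.dmrs, ds2.truth.dmrs)
        for g in GROUPS:
            pd.testing.assert_frame_equal(
                small_dataset.bs_tables[g][0], ds2.bs_tables[g][0]
            )
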