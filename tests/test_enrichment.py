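"""Tests for DMR-gene / peak-DMR association statistics."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylaxis.enrichment import (
    TssEnrichment,
    dmr_gene_hypergeom,
    enrichment_curve,
    gene_dmr_fraction,
    matched_control_band,
    pair_distances,
    peak_dmr_colocalization,
    tss_distance,
)
from methylaxis.simulate import simulate_genes


def brute_hypergeom_upper(k, M, K, n):
    """Exact rational upper-tail hypergeometric probability."""
    total = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, kk) * math.comb(M - K, n - kk), math.comb(M, n))
    return float(total)


def _genes(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df["name"] = [f"g{i}" for i in range(len(df))]
    df["tss"] = df["start"].where(df["strand"] == "+", df["end"] - 1)
    return df


def _dmrs(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestTssDistance:
    def test_plus_strand_downstream_positive(self):
        gene = {"chrom": "chr1", "tss": 1000, "strand": "+"}
        dmr = {"chrom": "chr1", "start": 1400, "end": 1600}
        assert tss_distance(dmr, gene) == 500

    def test_minus_strand_flips_sign(self):
        gene = {"chrom": "chr1", "tss": 1000, "strand": "-"}
        dmr = {"chrom": "chr1", "start": 1400, "end": 1600}
        assert tss_distance(dmr, gene) == -500

    def test_zero_at_tss(self):
        gene = {"chrom": "chr1", "tss": 1500, "strand": "+"}
        dmr = {"chrom": "chr1", "start": 1400, "end": 1600}
        assert tss_distance(dmr, gene) == 0

    def test_different_chromosomes_excluded(self):
        gene = {"chrom": "chr2", "tss": 1000, "strand": "+"}
        dmr = {"chrom": "chr1", "start": 0, "end": 10}
        assert tss_distance(dmr, gene) is None


class TestEnrichmentCurve:
    def test_hand_density(self):
        # 10 genes; 10 DMRs exactly at one gene's TSS; one 1-kb bin at zero
        genes = _genes([("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 500, "+") for i in range(10)])
        tss = genes["tss"].iloc[0]
        dmrs = _dmrs([("chr1", tss - 10, tss + 10)] * 10)
        curve = enrichment_curve(dmrs, genes, bins=[-500, 500])
        assert curve["score"].iloc[0] == pytest.approx(10 / (10 * 0.001))

    def test_no_dmrs_zero_curve(self):
        genes = _genes([("chr1", 1_000, 2_000, "+")])
        curve = enrichment_curve(_dmrs([]), genes)
        assert (curve["score"] == 0).all()

    def test_per_gene_normalization_invariant_to_duplication(self):
        genes = _genes([("chr1", 5_000, 6_000, "+"), ("chr1", 50_000, 51_000, "-")])
        dmrs = _dmrs([("chr1", 5_200, 5_400), ("chr1", 49_000, 49_100)])
        doubled = pd.concat([genes, genes.assign(name=genes["name"] + "_dup")], ignore_index=True)
        c1 = enrichment_curve(dmrs, genes)
        c2 = enrichment_curve(dmrs, doubled)
        np.testing.assert_allclose(c1["score"], c2["score"])

    def test_zero_width_bin_rejected(self):
        genes = _genes([("chr1", 1_000, 2_000, "+")])
        with pytest.raises(ValueError):
            enrichment_curve(_dmrs([("chr1", 0, 10)]), genes, bins=[0, 0, 100])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        genes = simulate_genes({"chr1": 3_000_000, "chr2": 2_000_000}, 30, rng, 1_000)
        starts = rng.integers(0, 2_000_000, 40)
        dmrs = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], 40), "start": starts, "end": starts + 200}
        )
        edges = np.arange(-1_000_000, 1_100_000, 100_000)
        curve = enrichment_curve(dmrs, genes, bins=edges)
        expected = np.zeros(len(edges) - 1)
        for _, g in genes.iterrows():
            for _, d in dmrs.iterrows():
                if d["chrom"] != g["chrom"]:
                    continue
                dist = (d["start"] + d["end"]) / 2.0 - g["tss"]
                if g["strand"] == "-":
                    dist = -dist
                b = np.searchsorted(edges, dist, side="right") - 1
                if 0 <= b < len(expected) and dist != edges[-1]:
                    expected[b] += 1
        expected /= len(genes) * 0.1
        np.testing.assert_allclose(curve["score"], expected, atol=1e-9)


class TestHypergeomTests:
    def test_hand_urn(self):
        # population 100, successes 20, sample 10, hits 5
        genes = [f"g{i}" for i in range(100)]
        flags = pd.Series([i < 20 for i in range(100)], index=genes)
        target = [f"g{i}" for i in range(15, 25)]  # exactly 5 flagged
        p = dmr_gene_hypergeom(target, genes, flags)
        assert p == pytest.approx(brute_hypergeom_upper(5, 100, 20, 10), rel=1e-9)
        # frozen value from the exact rational enumeration above
        assert p == pytest.approx(0.0254645464, abs=1e-9)

    def test_expected_proportion_middle_p(self):
        genes = [f"g{i}" for i in range(50)]
        flags = pd.Series([i < 25 for i in range(50)], index=genes)
        target = [f"g{i}" for i in range(20, 30)]  # 5 of 10 flagged = expectation
        p = dmr_gene_hypergeom(target, genes, flags)
        assert p == pytest.approx(brute_hypergeom_upper(5, 50, 25, 10), rel=1e-9)
        assert 0.5 <= p <= 0.7

    def test_no_successes_p_one(self):
        genes = [f"g{i}" for i in range(30)]
        flags = pd.Series(False, index=genes)
        assert dmr_gene_hypergeom(genes[:5], genes, flags) == 1.0

    def test_empty_target_is_error(self):
        with pytest.raises(ValueError):
            dmr_gene_hypergeom([], ["g0"], pd.Series({"g0": True}))

    def test_null_p_values_approximately_uniform(self):
        # uniform random DMR placement over exchangeable genes -> the
        # upper-tail p is (conservatively) uniform; KS should not reject
        rng = np.random.default_rng(12)
        genes = simulate_genes({"chr1": 30_000_000}, 2_000, rng, 2_000)
        target = rng.choice(genes["name"], 300, replace=False)
        ps = []
        for _ in range(500):
            starts = rng.integers(0, 30_000_000 - 200, 1_500)
            dmrs = pd.DataFrame({"chrom": "chr1", "start": np.sort(starts), "end": np.sort(starts) + 200})
            _, flags = gene_dmr_fraction(genes, dmrs, span=5_000)
            ps.append(dmr_gene_hypergeom(target, genes["name"], flags))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGeneDmrFraction:
    def test_no_dmrs(self):
        genes = _genes([("chr1", 0, 100, "+")])
        frac, flags = gene_dmr_fraction(genes, _dmrs([]))
        assert frac == 0.0
        assert not flags.any()

    def test_dmr_in_every_gene(self):
        genes = _genes([("chr1", i * 50_000, i * 50_000 + 1_000, "+") for i in range(4)])
        dmrs = _dmrs([("chr1", i * 50_000 + 100, i * 50_000 + 200) for i in range(4)])
        frac, _ = gene_dmr_fraction(genes, dmrs)
        assert frac == 1.0

    def test_hand_count(self):
        genes = _genes([("chr1", i * 100_000, i * 100_000 + 1_000, "+") for i in range(5)])
        dmrs = _dmrs(
            [
                ("chr1", 500, 600),          # inside gene 0
                ("chr1", 100_000 + 5_000, 100_000 + 5_100),  # within 10 kb span of gene 1
                ("chr1", 200_000 + 1_000 + 9_999, 200_000 + 1_000 + 10_050),  # 1 bp overlap of span
            ]
        )
        frac, flags = gene_dmr_fraction(genes, dmrs, span=10_000)
        assert frac == pytest.approx(0.6)
        assert flags.tolist() == [True, True, True, False, False]


class TestColocalization:
    def _peaks(self, centers, chrom="chr1", half=50):
        return pd.DataFrame(
            {"chrom": chrom, "start": np.asarray(centers) - half, "end": np.asarray(centers) + half}
        )

    def test_edge_at_max_dist_zero_counts_as_hit(self):
        dmrs = _dmrs([("chr1", 1_000, 1_200)])
        peaks = self._peaks([1_200])  # midpoint exactly at DMR end coordinate
        res = peak_dmr_colocalization(
            peaks, dmrs, max_dist=0, chrom_sizes={"chr1": 100_000}, window_bp=500
        )
        assert res.n_peaks_near_dmr == 1

    def test_zero_hits_p_one(self):
        dmrs = _dmrs([("chr1", 90_000, 90_100)])
        peaks = self._peaks([1_000, 5_000])
        res = peak_dmr_colocalization(
            peaks, dmrs, max_dist=100, chrom_sizes={"chr1": 100_000}, window_bp=500
        )
        assert res.n_peaks_near_dmr == 0
        assert res.p_value == 1.0

    def test_all_peaks_on_rare_dmrs_significant(self):
        # 10^4-window toy genome, successes rare, all peaks hit
        sizes = {"chr1": 5_000_000}
        dmr_centers = np.arange(100_000, 1_100_000, 100_000)
        dmrs = _dmrs([("chr1", c - 100, c + 100) for c in dmr_centers])
        peaks = self._peaks(dmr_centers)
        res = peak_dmr_colocalization(
            peaks, dmrs, max_dist=500, chrom_sizes=sizes, window_bp=500
        )
        assert res.universe_size == 10_000
        assert res.n_peaks_near_dmr == 10
        assert res.p_value < 1e-6
        assert res.p_value == pytest.approx(
            brute_hypergeom_upper(10, res.universe_size, res.n_successes, 10), rel=1e-9
        )

    def test_empty_peaks_error(self):
        with pytest.raises(ValueError):
            peak_dmr_colocalization(
                pd.DataFrame(columns=["chrom", "start", "end"]),
                _dmrs([("chr1", 0, 10)]),
                chrom_sizes={"chr1": 1_000},
            )


class TestMatchedControlBand:
    def _setup(self, seed=0, n_genes=200, n_dmrs=100):
        rng = np.random.default_rng(seed)
        genes = simulate_genes({"chr1": 20_000_000}, n_genes, rng, 2_000)
        starts = np.sort(rng.integers(0, 20_000_000 - 200, n_dmrs))
        dmrs = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 200})
        expr = pd.Series(rng.lognormal(5, 1, n_genes), index=genes["name"])
        targets = rng.choice(genes["name"], 30, replace=False)
        return genes, dmrs, expr, targets

    def test_single_resample_degenerates_to_single_curve(self):
        genes, dmrs, expr, targets = self._setup()
        band = matched_control_band(dmrs, targets, genes, expr, n_resamples=1, seed=5)
        np.testing.assert_allclose(band["band_low"], band["band_high"])

    def test_deterministic_given_seed(self):
        genes, dmrs, expr, targets = self._setup()
        b1 = matched_control_band(dmrs, targets, genes, expr, n_resamples=50, seed=7)
        b2 = matched_control_band(dmrs, targets, genes, expr, n_resamples=50, seed=7)
        pd.testing.assert_frame_equal(b1, b2)

    def test_implanted_target_enrichment_exceeds_band(self):
        genes, _, expr, targets = self._setup(seed=3)
        tg = genes[genes["name"].isin(targets)]
        dmrs = pd.DataFrame(
            {"chrom": "chr1", "start": tg["tss"].to_numpy() - 50, "end": tg["tss"].to_numpy() + 50}
        ).sort_values("start")
        band = matched_control_band(dmrs, targets, genes, expr, n_resamples=200, seed=4)
        zero_bin = band[(band["bin_left"] <= 0) & (band["bin_right"] > 0)].iloc[0]
        assert zero_bin["score"] > zero_bin["band_high"]

    def test_estimator_interface(self):
        genes, dmrs, expr, targets = self._setup(seed=8)
        est = TssEnrichment(n_resamples=50, seed=1)
        est.fit(dmrs, genes, target_genes=targets, expression=expr)
        assert est.band_ is not None
        assert len(est.curve_) == len(est.band_)
        params = est.get_params()
        assert params["n_resamples"] == 50


class TestPairDistances:
    def test_window_and_sign(self):
        genes = _genes([("chr1", 1_000_000, 1_002_000, "-")])
        dmrs = _dmrs([("chr1", 999_000, 999_200), ("chr1", 1_500_000, 1_500_100)])
        pairs = pair_distances(dmrs, genes, window=1_000_000)
        # minus-strand gene, tss = 1_001_999: upstream (larger coords) negative
        d = dict(zip(pairs["dmr_idx"], pairs["distance"]))
        assert d[0] == pytest.approx(1_001_999 - 999_100)
        assert d[1] == pytest.approx(1_001_999 - 1_500_050)
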