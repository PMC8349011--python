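"""Region signals, cross-species correlation, quartile bootstrap, PCA."""

import numpy as np
import pandas as pd
import pytest

from xrcompare.comparative import (
    genic_intergenic_split,
    pca_counts,
    quartile_bootstrap,
    region_signals,
    repair_correlation,
)
from xrcompare.homology import HomologPair
from xrcompare.io_core import GeneModel, GenomicInterval


def pair(pid, a_coords, b_coords):
    return HomologPair(
        pair_id=pid,
        region_a=GenomicInterval(*a_coords),
        region_b=GenomicInterval(*b_coords),
        identity=90.0,
    )


def read_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def reads_at(chrom, positions, length=26):
    return read_frame(
        [(chrom, p, p + length, ".", "0", "+") for p in positions]
    )


class TestRegionSignals:
    def _pairs(self):
        return [
            pair("p1", ("h1", 0, 1_000), ("m1", 0, 1_000)),
            pair("p2", ("h1", 2_000, 4_000), ("m1", 2_000, 4_000)),
            pair("p3", ("h1", 5_000, 5_500), ("m1", 5_000, 5_500)),
        ]

    def test_hand_computed_rpkm(self):
        pairs = self._pairs()
        xr = reads_at("h1", [10, 500, 2_100, 2_200, 3_000, 5_100])
        sim = reads_at("h1", [100, 2_500, 5_200, 900, 3_500])
        rna = reads_at("h1", [50, 2_050, 5_050])
        sig_a, sig_b = region_signals(
            pairs,
            {"xr": xr, "sim": sim, "rna": rna},
            {"xr": xr.assign(chrom="m1"), "sim": sim.assign(chrom="m1"),
             "rna": rna.assign(chrom="m1")},
        )
        assert len(sig_a) == 3
        # region p1: 2 xr reads, 1 kb, 6 total -> 2 / (1 * 6e-6)
        assert sig_a.loc[0, "xr_rpkm"] == pytest.approx(2 / (1.0 * 6e-6) / 1e6 * 1e6)
        assert sig_a.loc[0, "xr_rpkm"] == pytest.approx(
            2 / ((1_000 / 1_000) * (6 / 1e6)))
        # p2: 3 xr reads over 2 kb
        assert sig_a.loc[1, "xr_rpkm"] == pytest.approx(
            3 / ((2_000 / 1_000) * (6 / 1e6)))
        assert sig_a.loc[0, "norm_repair"] == pytest.approx(
            sig_a.loc[0, "xr_rpkm"] / sig_a.loc[0, "sim_rpkm"])

    def test_zero_xr_region_dropped_pairwise(self):
        pairs = self._pairs()
        xr_a = reads_at("h1", [10, 2_100, 2_200])        # nothing in p3
        xr_b = reads_at("m1", [10, 2_100, 5_100])
        sim = reads_at("h1", [100, 2_500, 5_200])
        rna = reads_at("h1", [50, 2_050, 5_050])
        sig_a, sig_b = region_signals(
            pairs,
            {"xr": xr_a, "sim": sim, "rna": rna},
            {"xr": xr_b, "sim": sim.assign(chrom="m1"),
             "rna": rna.assign(chrom="m1")},
        )
        assert list(sig_a["pair_id"]) == ["p1", "p2"]
        assert list(sig_b["pair_id"]) == ["p1", "p2"]

    def test_straddling_read_counted_once(self):
        pairs = [pair("p1", ("h1", 100, 200), ("m1", 100, 200))]
        # read overlaps the region boundary by one base
        xr = reads_at("h1", [75], length=26)
        one = reads_at("h1", [150])
        sig_a, _ = region_signals(
            pairs,
            {"xr": xr, "sim": one, "rna": one},
            {"xr": reads_at("m1", [150]), "sim": reads_at("m1", [150]),
             "rna": reads_at("m1", [150])},
        )
        assert sig_a.loc[0, "xr_count"] == 1

    def test_non_overlapping_read_not_counted(self):
        pairs = [pair("p1", ("h1", 100, 200), ("m1", 100, 200))]
        xr = reads_at("h1", [74], length=26)  # ends exactly at region start
        one = reads_at("h1", [150])
        with pytest.raises(ValueError):
            # p1 has zero XR overlap on side a -> dropped -> empty frames
            sig_a, _ = region_signals(
                pairs,
                {"xr": xr, "sim": one, "rna": one},
                {"xr": reads_at("m1", [150]), "sim": reads_at("m1", [150]),
                 "rna": reads_at("m1", [150])},
            )
            repair_correlation(sig_a, sig_a)

    def test_empty_pairs_error(self):
        with pytest.raises(ValueError, match="empty"):
            region_signals([], {}, {})


class TestRepairCorrelation:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        res = repair_correlation(x, x)
        assert res.r == pytest.approx(1.0)

    def test_reciprocal_vectors_anticorrelate_on_log_scale(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        res = repair_correlation(x, 1.0 / x)
        assert res.r == pytest.approx(-1.0)

    def test_symmetric(self, rng):
        x, y = np.exp(rng.normal(size=50)), np.exp(rng.normal(size=50))
        assert repair_correlation(x, y).r == pytest.approx(
            repair_correlation(y, x).r)

    def test_too_few_regions(self):
        with pytest.raises(ValueError, match=">= 3"):
            repair_correlation([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance(self):
        with pytest.raises(ValueError, match="variance"):
            repair_correlation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_spearman_option(self, rng):
        x = np.exp(rng.normal(size=30))
        res = repair_correlation(x, x ** 3, method="spearman")
        assert res.r == pytest.approx(1.0)


class TestQuartileBootstrap:
    def _signals(self, rng, n=80):
        base = np.exp(rng.normal(size=n))
        sig_a = pd.DataFrame({
            "pair_id": [f"p{i}" for i in range(n)],
            "rna_rpkm": np.exp(rng.normal(size=n)),
            "norm_repair": base * np.exp(0.3 * rng.normal(size=n)),
        })
        sig_b = pd.DataFrame({
            "pair_id": sig_a["pair_id"],
            "rna_rpkm": np.exp(rng.normal(size=n)),
            "norm_repair": base * np.exp(0.3 * rng.normal(size=n)),
        })
        return sig_a, sig_b

    def test_output_shape_and_reproducibility(self, rng):
        sig_a, sig_b = self._signals(rng)
        b1 = quartile_bootstrap(sig_a, sig_b, n_boot=10, seed=5)
        b2 = quartile_bootstrap(sig_a, sig_b, n_boot=10, seed=5)
        assert len(b1) == 2 * 4 * 10
        pd.testing.assert_frame_equal(b1, b2)
        assert b1["r"].between(-1, 1).all()

    def test_tied_expression_stable_split(self, rng):
        sig_a, sig_b = self._signals(rng, n=81)
        sig_a["rna_rpkm"] = 1.0
        boot = quartile_bootstrap(sig_a, sig_b, n_boot=2, seed=1)
        # rank-based split: sizes within one of each other even with ties
        assert set(boot["quartile"]) == {"Q1", "Q2", "Q3", "Q4"}

    def test_quartiles_partition_regions(self, rng):
        sig_a, sig_b = self._signals(rng, n=40)
        order = np.argsort(sig_a["rna_rpkm"].to_numpy(), kind="stable")
        quartiles = np.array_split(order, 4)
        flat = np.concatenate(quartiles)
        assert sorted(flat) == list(range(40))
        assert sum(len(q) for q in quartiles) == 40

    def test_tiny_quartile_errors(self, rng):
        sig_a, sig_b = self._signals(rng, n=8)
        with pytest.raises(ValueError, match="quartile"):
            quartile_bootstrap(sig_a, sig_b, n_boot=2, seed=0)


class TestPcaCounts:
    def _block_matrix(self, rng):
        n = 200
        base = np.exp(rng.normal(2, 1, n))
        group1 = np.exp(rng.normal(0, 1, n))
        group2 = np.exp(rng.normal(0, 1, n))
        cols = {}
        for k in range(3):
            cols[f"s1_{k}"] = rng.poisson(base * group1 * 50)
        for k in range(3):
            cols[f"s2_{k}"] = rng.poisson(base * group2 * 50)
        return pd.DataFrame(cols)

    def test_duplicated_samples_coincide(self, rng):
        counts = self._block_matrix(rng)
        counts["dup"] = counts["s1_0"]
        res = pca_counts(counts)
        coords = res.coordinates.set_index("sample")
        d = np.linalg.norm(
            coords.loc["dup", ["PC1", "PC2"]].to_numpy(dtype=float)
            - coords.loc["s1_0", ["PC1", "PC2"]].to_numpy(dtype=float)
        )
        spread = coords["PC1"].std()
        assert d < 1e-6 * max(spread, 1.0) + 1e-8

    def test_pc1_separates_blocks(self, rng):
        res = pca_counts(self._block_matrix(rng))
        coords = res.coordinates
        g1 = coords[coords["sample"].str.startswith("s1")]["PC1"]
        g2 = coords[coords["sample"].str.startswith("s2")]["PC1"]
        assert (g1.max() < g2.min()) or (g2.max() < g1.min())

    def test_sample_order_invariance_up_to_nothing(self, rng):
        counts = self._block_matrix(rng)
        res1 = pca_counts(counts)
        shuffled = counts[list(reversed(counts.columns))]
        res2 = pca_counts(shuffled)
        c1 = res1.coordinates.set_index("sample").loc[list(counts.columns)]
        c2 = res2.coordinates.set_index("sample").loc[list(counts.columns)]
        assert np.allclose(c1[["PC1", "PC2"]], c2[["PC1", "PC2"]], atol=1e-6)

    def test_constant_matrix_errors(self):
        counts = pd.DataFrame(np.ones((20, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            pca_counts(counts)

    def test_too_small_inputs(self):
        with pytest.raises(ValueError):
            pca_counts(pd.DataFrame(np.ones((5, 2)), columns=list("ab")))


class TestGenicIntergenicSplit:
    def test_partition(self):
        genes = [GeneModel("g", GenomicInterval("h1", 1_000, 5_000, "+"))]
        pairs = [
            pair("inside", ("h1", 2_000, 3_000), ("m1", 0, 1_000)),
            pair("touching", ("h1", 4_999, 6_000), ("m1", 2_000, 3_000)),
            pair("desert", ("h1", 50_000, 51_000), ("m1", 4_000, 5_000)),
        ]
        genic, intergenic = genic_intergenic_split(pairs, genes, side="a")
        assert [p.pair_id for p in genic] == ["inside", "touching"]
        assert [p.pair_id for p in intergenic] == ["desert"]

    def test_matches_bruteforce(self, rng, small_world):
        genes = small_world.gene_models("a")
        from xrcompare.homology import pairs_from_segments

        pairs = pairs_from_segments(small_world.segments())
        genic, intergenic = genic_intergenic_split(pairs, genes, side="a")
        for p in pairs:
            hit = any(p.region_a.overlaps(g.interval) for g in genes)
            assert (p in genic) == hit
            assert (p in intergenic) == (not hit)
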