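"""TS/NTS metagene machinery: isolation filter, RPKM, shuffle, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xrcompare.io_core import GeneModel, GenomicInterval
from xrcompare.repair_profiles import (
    filter_isolated_genes,
    gene_asymmetry,
    metagene_profile,
    rpkm,
    shuffle_reads,
    ts_nts_test,
)
from xrcompare.synthetic_data import simulate_xr_reads, tcr_world_config, build_world


def gene(gid, chrom, start, end, strand="+"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand))


def read_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


class TestFilterIsolatedGenes:
    def test_distant_genes_kept(self):
        genes = [gene("a", "c", 0, 1_000), gene("b", "c", 26_000, 27_000)]
        assert filter_isolated_genes(genes) == genes

    def test_boundary_pair_removed(self):
        genes = [gene("a", "c", 0, 1_000), gene("b", "c", 20_999, 22_000)]
        assert filter_isolated_genes(genes) == []

    def test_exactly_min_gap_kept(self):
        genes = [gene("a", "c", 0, 1_000), gene("b", "c", 21_000, 22_000)]
        assert filter_isolated_genes(genes) == genes

    def test_overlapping_genes_removed(self):
        genes = [gene("a", "c", 0, 5_000), gene("b", "c", 2_000, 7_000),
                 gene("far", "c", 50_000, 51_000)]
        assert filter_isolated_genes(genes) == [genes[2]]

    def test_different_chromosomes_independent(self):
        genes = [gene("a", "c1", 0, 1_000), gene("b", "c2", 500, 1_500)]
        assert filter_isolated_genes(genes) == genes

    def test_random_genes_match_bruteforce(self, rng):
        genes = []
        for i in range(100):
            s = int(rng.integers(0, 400_000))
            genes.append(gene(f"g{i}", f"c{rng.integers(1, 3)}",
                              s, s + int(rng.integers(500, 3_000))))
        got = {g.gene_id for g in filter_isolated_genes(genes)}
        bad = set()
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                if a.chrom != b.chrom:
                    continue
                d = max(0, max(a.start, b.start) - min(a.end, b.end))
                if d < 20_000:
                    bad |= {a.gene_id, b.gene_id}
        assert got == {g.gene_id for g in genes} - bad


class TestRpkm:
    def test_closed_form(self):
        assert rpkm(10, 1_000, 1_000_000) == pytest.approx(10.0)

    def test_zero_count(self):
        assert rpkm(0, 500, 1_000) == 0.0

    def test_doubling_total_halves_value(self):
        assert rpkm(7, 800, 2_000_000) == pytest.approx(rpkm(7, 800, 1_000_000) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestShuffleReads:
    def test_conserves_count_and_length_multiset(self, rng):
        lengths = rng.integers(16, 31, 2_000)
        reads = read_frame(
            [("c1", int(s), int(s + l), ".", "0", "+")
             for s, l in zip(rng.integers(0, 90_000, 2_000), lengths)]
        )
        out = shuffle_reads(reads, {"c1": 100_000, "c2": 50_000}, seed=1)
        assert len(out) == 2_000
        assert sorted(out["end"] - out["start"]) == sorted(lengths)

    def test_positions_uniform_chisquare(self, rng):
        reads = read_frame([("c1", 0, 26, ".", "0", "+")] * 100_000)
        out = shuffle_reads(reads, {"c1": 500_000}, seed=2)
        counts, _ = np.histogram(out["start"], bins=50, range=(0, 500_000 - 26))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=49) > 1e-4

    def test_chromosome_choice_proportional_to_length(self, rng):
        reads = read_frame([("c1", 0, 26, ".", "0", "+")] * 30_000)
        out = shuffle_reads(reads, {"c1": 300_000, "c2": 100_000}, seed=3)
        frac = (out["chrom"] == "c1").mean()
        assert frac == pytest.approx(0.75, abs=0.01)

    def test_seed_reproducibility(self):
        reads = read_frame([("c1", 0, 26, ".", "0", "+")] * 100)
        a = shuffle_reads(reads, {"c1": 10_000}, seed=9)
        b = shuffle_reads(reads, {"c1": 10_000}, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestMetageneProfile:
    def _uniform_reads(self, rng, n, size=400_000):
        starts = rng.integers(0, size - 26, n)
        return read_frame(
            [("c", int(s), int(s) + 26, ".", "0",
              "+" if rng.random() < 0.5 else "-") for s in starts]
        )

    def test_uniform_reads_give_flat_unit_profile(self, rng):
        genes = [gene("g1", "c", 150_000, 160_000, "+"),
                 gene("g2", "c", 250_000, 256_000, "-")]
        reads = self._uniform_reads(rng, 60_000)
        shuffled = shuffle_reads(reads, {"c": 400_000}, seed=4)
        prof = metagene_profile(reads, genes, shuffled, anchor="TSS",
                                chrom_sizes={"c": 400_000})
        for arr in (prof.ts_norm, prof.nts_norm):
            assert abs(arr.mean() - 1.0) < 0.1

    def test_minus_strand_gene_orientation(self):
        """For a minus-strand gene, a plus-strand read downstream of the
        TSS is transcribed-strand repair and lands in a downstream bin."""
        g = gene("g", "c", 50_000, 60_000, "-")  # TSS at 60,000
        reads = read_frame([("c", 59_000, 59_026, ".", "0", "+")])
        shuffled = read_frame([("c", int(s), int(s) + 26, ".", "0", "+")
                               for s in np.linspace(40_000, 70_000, 500)])
        prof = metagene_profile(reads, [g], shuffled, anchor="TSS",
                                chrom_sizes={"c": 200_000})
        assert prof.ts_rpkm.sum() > 0
        assert prof.nts_rpkm.sum() == 0
        hit = int(np.flatnonzero(prof.ts_rpkm > 0)[0])
        # ~1 kb downstream of TSS in transcription direction: bin 100 + 9
        assert hit == 109

    def test_bin_count_and_offsets(self, rng):
        genes = [gene("g", "c", 100_000, 110_000, "+")]
        reads = self._uniform_reads(rng, 1_000)
        prof = metagene_profile(reads, genes, reads, anchor="TES",
                                chrom_sizes={"c": 400_000})
        assert len(prof.ts_norm) == 200
        assert prof.offsets[0] == -9_950 and prof.offsets[-1] == 9_950

    def test_zero_shuffled_reads_errors(self, rng):
        genes = [gene("g", "c", 100_000, 110_000, "+")]
        reads = self._uniform_reads(rng, 100)
        with pytest.raises(ValueError, match="shuffled"):
            metagene_profile(reads, genes, reads.iloc[:0], anchor="TSS")

    def test_counts_conserved_within_windows(self, rng):
        """Pooled binned counts never exceed the total read count for
        non-overlapping windows."""
        genes = [gene("g1", "c", 100_000, 110_000, "+"),
                 gene("g2", "c", 200_000, 210_000, "+")]
        reads = self._uniform_reads(rng, 5_000)
        from xrcompare.repair_profiles import _binned_counts

        ts, nts, _ = _binned_counts(reads, genes, "TSS", 10_000, 100,
                                    {"c": 400_000})
        assert ts.sum() + nts.sum() <= 5_000


class TestAsymmetryRecovery:
    def test_planted_asymmetry_recovered_via_metagene(self):
        """World with TS:NTS odds 2 -> pooled TSS-downstream ratio near 2,
        upstream near 1."""
        w = build_world(tcr_world_config(asymmetry=2.0, seed=13, n_genes=150))
        genes = filter_isolated_genes(w.gene_models("a"))
        reads = simulate_xr_reads(w, "a", n_reads=120_000, seed=14)
        sizes = w.chrom_sizes["a"]
        shuffled = shuffle_reads(reads, sizes, seed=15)
        prof = metagene_profile(reads, genes, shuffled, anchor="TSS",
                                chrom_sizes=sizes)
        down = slice(100, 200)
        ratio_down = prof.ts_norm[down].sum() / prof.nts_norm[down].sum()
        ratio_up = prof.ts_norm[:100].sum() / prof.nts_norm[:100].sum()
        assert 1.7 <= ratio_down <= 2.3
        assert abs(ratio_up - 1.0) < 0.25


class TestTsNtsTest:
    def test_identical_groups_not_significant(self):
        ratios = list(np.linspace(1.0, 3.0, 20))
        res = ts_nts_test(ratios, ratios)
        assert res.p_value > 0.9
        assert res.median_a == res.median_b

    def test_complete_separation(self):
        res = ts_nts_test([2.0] * 12, [1.0] * 12)
        assert res.u_statistic == 12 * 12
        assert res.p_value < 0.01

    def test_nan_ratios_dropped(self):
        res = ts_nts_test([1.0, 2.0, np.nan], [1.5, 2.5])
        assert res.n_a == 2 and res.n_b == 2

    def test_all_undefined_errors(self):
        with pytest.raises(ValueError):
            ts_nts_test([np.nan, np.nan], [1.0, 2.0])


class TestGeneAsymmetry:
    def test_reads_opposite_gene_strand_are_ts(self):
        g = gene("g", "c", 10_000, 15_000, "+")
        reads = read_frame(
            [("c", 11_000, 11_026, ".", "0", "-")] * 4
            + [("c", 12_000, 12_026, ".", "0", "+")] * 2
        )
        out = gene_asymmetry(reads, [g])
        assert out.loc[0, "ratio"] == pytest.approx(2.0)

    def test_zero_nts_gives_nan_ratio(self):
        g = gene("g", "c", 10_000, 15_000, "+")
        reads = read_frame([("c", 11_000, 11_026, ".", "0", "-")])
        out = gene_asymmetry(reads, [g])
        assert np.isnan(out.loc[0, "ratio"])
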