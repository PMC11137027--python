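"""Normalization factors, background correction, regions, differential logic."""

import numpy as np
import pandas as pd
import pytest

import nucshift as ns
from nucshift.normalize import apply_factors, choose_reference


def libstats(i, condition="control", mouse=10_000, spike=1_000, ref=False):
    return ns.LibraryStats(f"lib{i}", condition, mouse, spike, ref)


class TestLibsize:
    def test_cpm_arithmetic(self):
        assert ns.libsize_normalize(200, 2e6) == pytest.approx(100.0)

    def test_whole_library_normalizes_to_one_million(self, rng):
        counts = rng.integers(0, 100, size=400)
        dens = ns.libsize_normalize(counts, counts.sum())
        assert dens.sum() == pytest.approx(1e6)

    def test_proportional_libraries_equalize(self, rng):
        counts = rng.integers(1, 100, size=50)
        np.testing.assert_allclose(
            ns.libsize_normalize(counts, counts.sum()),
            ns.libsize_normalize(5 * counts, 5 * counts.sum()),
        )

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            ns.libsize_normalize(np.ones(3), 0)


class TestSpikeIn:
    def test_identical_libraries_get_equal_factors(self):
        stats = [libstats(i) for i in range(4)]
        f = ns.spikein_factors(stats)
        assert (f == f.iloc[0]).all()

    def test_doubling_spike_reads_halves_normalized_signal(self):
        stats = [libstats(0), libstats(1, spike=2_000)]
        f = ns.spikein_factors(stats)
        counts = pd.DataFrame({"lib0": [100], "lib1": [100]})
        dens = apply_factors(counts, f)
        assert dens.loc[0, "lib1"] == pytest.approx(dens.loc[0, "lib0"] / 2)

    def test_factor_formula(self):
        stats = [
            libstats(0, mouse=8_000, spike=1_000, ref=True),
            libstats(1, "depleted", mouse=12_000, spike=3_000),
        ]
        f = ns.spikein_factors(stats)
        mean_mouse = 10_000
        assert f["lib0"] == pytest.approx(mean_mouse * 1.0)
        assert f["lib1"] == pytest.approx(mean_mouse * 3.0)

    def test_permutation_equivariance(self):
        stats = [libstats(0, ref=True)] + [
            libstats(i, spike=500 * i) for i in (1, 2, 3)
        ]
        f1 = ns.spikein_factors(stats)
        f2 = ns.spikein_factors([stats[0], stats[3], stats[1], stats[2]])
        pd.testing.assert_series_equal(f1.sort_index(), f2.sort_index())

    def test_reference_requirements(self):
        with pytest.raises(ValueError):
            ns.spikein_factors([libstats(0, ref=True), libstats(1, ref=True)])
        with pytest.raises(ValueError):
            ns.spikein_factors([libstats(0, condition="depleted")])
        assert choose_reference(
            [libstats(0, spike=100), libstats(1, spike=300), libstats(2, spike=200)]
        ).library_id == "lib2"

    def test_zero_spike_reads_rejected(self):
        with pytest.raises(ValueError):
            ns.LibraryStats("x", "control", 10, -1)
        s = libstats(0)
        s.spike_reads = 0
        with pytest.raises(ValueError):
            ns.spikein_factors([s])

    def test_recovery_from_simulated_cohort(self):
        rng = np.random.default_rng(8)
        specs = [
            ns.SpikeInSimSpec(
                f"lib{i}", "control" if i < 10 else "depleted",
                mouse_reads=1_000_000, spike_reads=50_000,
                true_global_factor=float(rng.uniform(0.5, 2.0)),
            )
            for i in range(20)
        ]
        matrix, stats = ns.simulate_spikein_libraries(specs, regions=300, seed=44)
        f = ns.spikein_factors(stats)
        truth = pd.Series({s.library_id: s.true_global_factor for s in specs})
        r = np.corrcoef(f[truth.index], truth)[0, 1]
        assert r > 0.95


class TestConservedGenes:
    def _genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "chrom": "chr1",
                "start": [10_000, 50_000, 90_000],
                "end": [20_000, 60_000, 100_000],
                "strand": ["+", "+", "-"],
            }
        )

    def test_cpm_threshold_boundary(self):
        genes = self._genes()
        # library size 1e6 so counts are CPM directly
        counts = pd.DataFrame(
            {"libA": [501, 499, 800], "libB": [600, 700, 900]},
            index=genes["gene_id"],
        )
        sizes = pd.Series({"libA": 1e6, "libB": 1e6})
        peaks = pd.DataFrame({"chrom": [], "start": [], "end": []})
        _, selected = ns.conserved_gene_factors(genes, counts, peaks, library_sizes=sizes)
        assert selected == ["g1", "g3"]  # g2 fails 500 CPM in libA

    def test_brg1_overlap_excludes_gene(self):
        genes = self._genes()
        counts = pd.DataFrame(
            {"libA": [800, 800, 800], "libB": [800, 800, 800]}, index=genes["gene_id"]
        )
        sizes = pd.Series({"libA": 1e6, "libB": 1e6})
        # peak 1 kb upstream of g1 (inside its 2 kb promoter pad)
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [8_500], "end": [9_200]})
        _, selected = ns.conserved_gene_factors(genes, counts, peaks, library_sizes=sizes)
        assert selected == ["g2", "g3"]

    def test_factor_doubles_with_depth(self):
        genes = self._genes()
        counts = pd.DataFrame(
            {"libA": [1000, 1000, 1000], "libB": [2000, 2000, 2000]},
            index=genes["gene_id"],
        )
        sizes = pd.Series({"libA": 1e6, "libB": 1e6})
        peaks = pd.DataFrame({"chrom": [], "start": [], "end": []})
        factors, _ = ns.conserved_gene_factors(genes, counts, peaks, library_sizes=sizes)
        assert factors["libB"] / factors["libA"] == pytest.approx(2.0)
        dens = apply_factors(counts, factors, scale=1.0)
        np.testing.assert_allclose(dens["libA"], dens["libB"])

    def test_no_genes_selected_is_diagnosed(self):
        genes = self._genes()
        counts = pd.DataFrame(
            {"libA": [10, 10, 10], "libB": [10, 10, 10]}, index=genes["gene_id"]
        )
        sizes = pd.Series({"libA": 1e6, "libB": 1e6})
        peaks = pd.DataFrame({"chrom": [], "start": [], "end": []})
        with pytest.raises(ValueError, match="closest"):
            ns.conserved_gene_factors(genes, counts, peaks, library_sizes=sizes)


class TestBackgroundCorrect:
    def test_signal_equal_to_background_vanishes(self):
        out = ns.background_correct([100], [1_000], 1_000_000, 10_000_000 + 1_000)
        # in-peak density 0.1 equals background 1e6/1e7 = 0.1
        assert out[0] == pytest.approx(0.0)

    def test_zero_background_is_identity_density(self):
        out = ns.background_correct([100], [1_000], 0, 1e9)
        assert out[0] == pytest.approx(0.1)

    def test_hand_computed_case(self):
        # peak 1 kb with 100 reads; background 1e6 reads over ~1e9 bp
        out = ns.background_correct([100], [1_000], 1_000_000, 1_000_000_000 + 1_000)
        assert out[0] == pytest.approx(0.1 - 0.001)

    def test_floors_at_zero_and_validates(self):
        out = ns.background_correct([1], [1_000], 1_000_000, 2_000_000)
        assert out[0] == 0.0
        with pytest.raises(ValueError):
            ns.background_correct([1], [0], 0, 1e6)
        with pytest.raises(ValueError):
            ns.background_correct([1], [1_000], 0, 500)


class TestRegions:
    def _tss(self):
        return pd.DataFrame(
            {
                "anchor_id": ["t1"],
                "chrom": ["chr1"],
                "position": [100_000],
                "strand": ["+"],
            }
        )

    def test_peak_distance_classes(self):
        tss = self._tss()
        peaks = pd.DataFrame(
            {
                "region_id": ["near", "far", "middle"],
                "chrom": "chr1",
                # midpoints at 1.9 kb, 6 kb and 3 kb from the TSS
                "start": [101_850, 105_950, 102_950],
                "end": [101_950, 106_050, 103_050],
            }
        )
        out = ns.make_regions(tss, peaks=peaks)
        kinds = out.set_index("region_id")["kind"]
        assert kinds["near"] == "TSS"
        assert kinds["far"] == "nonTSS"
        assert "middle" not in kinds.index

    def test_five_and_three_prime_windows(self):
        tss = self._tss()
        tts = pd.DataFrame(
            {"anchor_id": ["t1"], "chrom": ["chr1"], "position": [130_000], "strand": ["+"]}
        )
        out = ns.make_regions(tss, tts=tts)
        five = out[out["kind"] == "fivePrime"].iloc[0]
        assert (five["start"], five["end"]) == (99_000, 101_000)
        three = out[out["kind"] == "threePrime"].iloc[0]
        assert (three["start"], three["end"]) == (129_000, 131_000)

    def test_missing_strand_rejected(self):
        tss = self._tss().drop(columns="strand")
        with pytest.raises(ValueError):
            ns.make_regions(tss)


class TestDifferentialSummary:
    def test_joint_cutoff_and_partition(self):
        df = pd.DataFrame(
            {
                "p_value": [0.01, 0.01, 0.2, 0.04, 0.01],
                "fold_change": [0.5, 1.5, 0.4, 1.2, 1.31],
            }
        )
        s = ns.differential_summary(df)
        # row 2 fails p, row 4 fails fold-change cutoff (1.2 < 1.3)
        assert s["n_changed"] == 3
        assert s["n_changed"] == s["n_down"] + s["n_up"]
        assert s["n_down"] == 1

    def test_reported_fraction_arithmetic(self):
        # 8305 changed sites of which 7987 decreased
        df = pd.DataFrame(
            {
                "p_value": [0.001] * 8305,
                "fold_change": [0.5] * 7987 + [2.0] * 318,
            }
        )
        s = ns.differential_summary(df)
        assert s["pct_down_of_changed"] == pytest.approx(96.17, abs=0.01)

    def test_no_significant_regions_flagged(self):
        df = pd.DataFrame({"p_value": [0.9], "fold_change": [1.0]})
        s = ns.differential_summary(df)
        assert s["n_changed"] == 0 and np.isnan(s["pct_down_of_changed"])

    def test_all_down(self):
        df = pd.DataFrame({"p_value": [0.01] * 4, "fold_change": [0.2] * 4})
        assert ns.differential_summary(df)["pct_down_of_changed"] == 100.0

    def test_nonpositive_fold_change_rejected(self):
        df = pd.DataFrame({"p_value": [0.01], "fold_change": [0.0]})
        with pytest.raises(ValueError):
            ns.differential_summary(df)


class TestTertiles:
    def test_one_to_nine(self):
        labels = ns.tertile_groups(np.arange(1, 10))
        assert list(labels[:3]) == ["low"] * 3
        assert list(labels[3:6]) == ["medium"] * 3
        assert list(labels[6:]) == ["high"] * 3

    def test_ties_stable_and_balanced(self):
        labels = ns.tertile_groups(np.zeros(7))
        sizes = pd.Series(labels).value_counts()
        assert sizes.max() - sizes.min() <= 1
        # stability: first values get 'low'
        assert labels[0] == "low"

    @pytest.mark.parametrize("n", range(3, 31))
    def test_group_sizes_differ_by_at_most_one(self, n):
        rng = np.random.default_rng(n)
        labels = ns.tertile_groups(rng.random(n))
        sizes = pd.Series(labels).value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert set(sizes.index) == {"low", "medium", "high"}

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ns.tertile_groups([1, 2])
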