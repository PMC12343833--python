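import numpy as np
import pytest

from topoturn import (
    CoverageTrack,
    FragmentSet,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SimScenario,
    binned_correlation,
    build_synthetic_genome,
    combine_replicates,
    coverage_from_fragments,
    log2_ratio_track,
    simulate_cutrun_fragments,
    spike_in_scale,
    znormalize_track,
)

from conftest import oracle_bin_means, oracle_depth, random_intervals, random_layout


def frags(ivs, spike=100):
    return FragmentSet(IntervalSet(list(ivs)), spike_in_count=spike)


def make_track(layout, values, bin_size=50, state="raw"):
    return CoverageTrack(layout, bin_size, values, state)


class TestCoverageFromFragments:
    def test_single_fragment_two_full_bins(self):
        layout = GenomeLayout([("chr1", 1000)])
        t = coverage_from_fragments(frags([GenomicInterval("chr1", 0, 100)]), layout, 50)
        assert t.values["chr1"][0] == 1.0 and t.values["chr1"][1] == 1.0
        assert t.values["chr1"][2:].sum() == 0
        assert t.normalization_state == "raw"

    def test_partial_bin_matches_per_base_oracle(self):
        layout = GenomeLayout([("chr1", 1000)])
        t = coverage_from_fragments(frags([GenomicInterval("chr1", 0, 75)]), layout, 50)
        assert t.values["chr1"][0] == 1.0
        assert t.values["chr1"][1] == 0.5

    def test_empty_fragment_set_all_zero(self, tiny_layout):
        t = coverage_from_fragments(frags([]), tiny_layout, 10)
        assert t.all_values().sum() == 0

    def test_mass_conservation_random(self, rng):
        """Sum(bin value * bin width) equals total fragment base pairs."""
        for _ in range(20):
            layout = random_layout(rng, max_len=8000)
            fs = frags(random_intervals(rng, layout, n_max=40))
            bin_size = int(rng.choice([1, 7, 10, 64]))
            t = coverage_from_fragments(fs, layout, bin_size)
            # bin value is (fragment bp in bin) / bin_size, so total mass
            # Sum(value * bin_size) returns exactly the fragment bp
            mass = float(t.all_values().sum()) * bin_size
            expected = float(sum(len(iv) for iv in fs.fragments))
            assert mass == pytest.approx(expected, abs=1e-6)
            oracle = oracle_bin_means(
                oracle_depth(fs.fragments, layout), layout, bin_size
            )
            for c, _ in layout.chromosomes:
                np.testing.assert_allclose(t.values[c], oracle[c], atol=1e-9)


class TestSpikeInScale:
    def test_factor_one_is_identity(self, tiny_layout):
        t = coverage_from_fragments(
            frags([GenomicInterval("chr1", 0, 100)]), tiny_layout, 50
        )
        s = spike_in_scale(t, 10_000, scale_constant=10_000)
        np.testing.assert_array_equal(s.values["chr1"], t.values["chr1"])
        assert s.normalization_state == "spike_scaled"

    def test_doubling_spike_halves_values(self, tiny_layout):
        t = coverage_from_fragments(
            frags([GenomicInterval("chr1", 0, 100)]), tiny_layout, 50
        )
        a = spike_in_scale(t, 100)
        b = spike_in_scale(t, 200)
        np.testing.assert_allclose(b.all_values(), a.all_values() / 2)

    def test_zero_spike_count_rejected(self, tiny_layout):
        t = coverage_from_fragments(frags([]), tiny_layout, 50)
        with pytest.raises(ValueError):
            spike_in_scale(t, 0)

    def test_depth_invariance_of_scaled_tracks(self):
        """The same library sequenced twice as deep (spike count scaling
        with depth) yields the same spike-scaled signal."""
        sc1 = SimScenario(
            n_chromosomes=1, chromosome_length=400_000, n_genes=40,
            n_hotspots=30, n_domains=20, cutrun_fragment_count=30_000,
            rng_seed=5,
        )
        _, _, truth = build_synthetic_genome(sc1)
        import dataclasses

        sc2 = dataclasses.replace(sc1, cutrun_fragment_count=60_000)
        shallow = simulate_cutrun_fragments(truth, "TOP1", sc1, seed=1)
        deep = simulate_cutrun_fragments(truth, "TOP1", sc2, seed=2)
        t1 = spike_in_scale(
            coverage_from_fragments(shallow, truth.layout, 100),
            shallow.spike_in_count,
        )
        t2 = spike_in_scale(
            coverage_from_fragments(deep, truth.layout, 100),
            deep.spike_in_count,
        )
        from topoturn import region_mean_signal

        m1 = np.nanmean(region_mean_signal(t1, truth.hotspots))
        m2 = np.nanmean(region_mean_signal(t2, truth.hotspots))
        # spike counts ~ Binomial(n, 0.05) give the ratio a ~4% CV; 0.12 is
        # a 3-sigma band for this library size
        assert abs(m1 / m2 - 1) < 0.12


class TestZNormalize:
    def test_closed_form_population_sd(self):
        layout = GenomeLayout([("chr1", 150)])
        t = make_track(layout, {"chr1": np.array([1.0, 2.0, 3.0])})
        z = znormalize_track(t)
        np.testing.assert_allclose(
            z.values["chr1"], [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_mean_zero_sd_one(self, rng):
        layout = GenomeLayout([("chr1", 5000)])
        t = make_track(layout, {"chr1": rng.normal(5, 3, 100)})
        z = znormalize_track(t)
        assert abs(z.all_values().mean()) < 1e-9
        assert abs(z.all_values().std() - 1) < 1e-9

    def test_idempotent_within_tolerance(self, rng):
        layout = GenomeLayout([("chr1", 5000)])
        t = make_track(layout, {"chr1": rng.normal(0, 2, 100)})
        z1 = znormalize_track(t)
        z2 = znormalize_track(z1.copy_with(z1.values, "raw"))
        np.testing.assert_allclose(z1.all_values(), z2.all_values(), atol=1e-9)

    def test_constant_track_rejected(self):
        layout = GenomeLayout([("chr1", 150)])
        t = make_track(layout, {"chr1": np.full(3, 7.0)})
        with pytest.raises(ValueError):
            znormalize_track(t)


class TestCombineReplicates:
    def test_average_of_identical_is_identity(self, rng):
        layout = GenomeLayout([("chr1", 500)])
        t = make_track(layout, {"chr1": rng.random(10)})
        avg = combine_replicates([t, t], "average_tracks")
        np.testing.assert_array_equal(avg.values["chr1"], t.values["chr1"])

    def test_binwise_mean(self):
        layout = GenomeLayout([("chr1", 100)])
        a = make_track(layout, {"chr1": np.array([0.0, 0.0])})
        b = make_track(layout, {"chr1": np.array([2.0, 4.0])})
        avg = combine_replicates([a, b], "average_tracks")
        np.testing.assert_array_equal(avg.values["chr1"], [1.0, 2.0])

    def test_merge_fragments_conserves(self):
        f1 = frags([GenomicInterval("chr1", 0, 10)] * 100, spike=30)
        f2 = frags([GenomicInterval("chr1", 50, 60)] * 50, spike=12)
        merged = combine_replicates([f1, f2], "merge_fragments")
        assert len(merged) == 150 and merged.spike_in_count == 42

    def test_state_mismatch_rejected(self):
        layout = GenomeLayout([("chr1", 100)])
        a = make_track(layout, {"chr1": np.array([1.0, 1.0])}, state="raw")
        b = make_track(layout, {"chr1": np.array([1.0, 1.0])}, state="spike_scaled")
        with pytest.raises(ValueError, match="normalization state"):
            combine_replicates([a, b], "average_tracks")


class TestLog2Ratio:
    def _pair(self, vals_a, vals_b):
        assert len(vals_a) == len(vals_b)
        layout = GenomeLayout([("chr1", 50 * len(vals_a))])
        a = make_track(layout, {"chr1": np.asarray(vals_a, float)})
        b = make_track(layout, {"chr1": np.asarray(vals_b, float)})
        return a, b

    def test_self_ratio_zero_on_unmasked(self):
        a, _ = self._pair([1.0, 2.0, 0.0, 5.0], [0.0, 0.0, 0.0, 0.0])
        r = log2_ratio_track(a, a)
        vals = r.values["chr1"]
        assert np.isnan(vals[2])  # both zero -> masked
        np.testing.assert_array_equal(vals[[0, 1, 3]], 0.0)

    def test_doubling_gives_one(self):
        a, b = self._pair([2000.0, 4000.0], [1000.0, 2000.0])
        r = log2_ratio_track(a, b, pseudocount=0.5)
        np.testing.assert_allclose(r.values["chr1"], 1.0, atol=1e-3)

    def test_antisymmetry(self, rng):
        layout = GenomeLayout([("chr1", 1000)])
        a = make_track(layout, {"chr1": rng.random(20) * 10})
        b = make_track(layout, {"chr1": rng.random(20) * 10})
        ab = log2_ratio_track(a, b).values["chr1"]
        ba = log2_ratio_track(b, a).values["chr1"]
        np.testing.assert_allclose(ab, -ba, atol=1e-12)

    def test_state_mismatch_rejected(self):
        a, b = self._pair([1.0], [1.0])
        b2 = b.copy_with(b.values, "spike_scaled")
        with pytest.raises(ValueError, match="state"):
            log2_ratio_track(a, b2)


class TestBinnedCorrelation:
    def test_self_monotone_and_negation(self, rng):
        layout = GenomeLayout([("chr1", 200_000)])
        vals = rng.random(20)
        t = make_track(layout, {"chr1": vals}, bin_size=10_000)
        cube = make_track(layout, {"chr1": vals**3}, bin_size=10_000)
        neg = make_track(layout, {"chr1": -vals}, bin_size=10_000)
        mat = binned_correlation([t, cube, neg], bin_size=10_000)
        assert mat[0, 0] == 1.0
        assert mat[0, 1] == pytest.approx(1.0)  # rank-invariant
        assert mat[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(mat, mat.T)
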