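import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from topoturn import (
    GeneTable,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    classify_tss_proximity,
    flatten,
    jaccard_index,
    permutation_colocalization,
    shuffle_intervals,
)

from conftest import oracle_jaccard, random_intervals, random_layout


class TestFlatten:
    @pytest.mark.parametrize(
        "spans, expected",
        [
            ([(0, 10), (5, 15)], [(0, 15)]),
            ([(0, 10), (20, 30)], [(0, 10), (20, 30)]),
            ([(0, 10), (10, 20)], [(0, 20)]),
        ],
        ids=["overlap", "disjoint", "abutting"],
    )
    def test_merging(self, spans, expected):
        iset = IntervalSet([GenomicInterval("chr1", s, e) for s, e in spans])
        out = flatten(iset)
        assert [(iv.start, iv.end) for iv in out] == expected

    def test_covered_bp_preserved_random(self, rng):
        for _ in range(30):
            layout = random_layout(rng, 5000)
            iset = random_intervals(rng, layout, n_max=25)
            flat = flatten(iset)
            # no overlaps/abutments remain
            by_chrom = {}
            for iv in flat:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for ivs in by_chrom.values():
                for a, b in zip(ivs, ivs[1:]):
                    assert a.end < b.start
            from conftest import bitmap

            bm = bitmap(iset, layout)
            covered = sum(int(v.sum()) for v in bm.values())
            assert flat.total_bp() == covered


class TestJaccard:
    def test_identical_sets_full_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 5, 50)])
        assert jaccard_index(a, a) == 1.0

    def test_disjoint_sets_zero(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 50, 60)])
        assert jaccard_index(a, b) == 0.0

    def test_hand_counted_partial_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 5, 15)])
        assert jaccard_index(a, b) == pytest.approx(5 / 15)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            jaccard_index(IntervalSet([]), IntervalSet([]))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bitmap_oracle_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        layout = random_layout(rng, 4000)
        a = random_intervals(rng, layout, n_max=15)
        b = random_intervals(rng, layout, n_max=15)
        if len(a) == 0 and len(b) == 0:
            return
        j = jaccard_index(a, b)
        assert 0.0 <= j <= 1.0
        assert j == pytest.approx(oracle_jaccard(a, b, layout))
        assert j == jaccard_index(b, a)

    def test_agrees_with_bedtools(self, tmp_path, rng):
        """External oracle: bedtools jaccard on a random fixture."""
        import shutil, subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools not on PATH")
        layout = GenomeLayout([("chr1", 10_000), ("chr2", 8_000)])
        a = flatten(random_intervals(rng, layout, n_max=12, label="a"))
        b = flatten(random_intervals(rng, layout, n_max=12, label="b"))
        from topoturn import write_bed

        pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(a, pa)
        write_bed(b, pb)
        out = subprocess.run(
            ["bedtools", "jaccard", "-a", str(pa), "-b", str(pb)],
            capture_output=True, text=True, check=True,
        ).stdout.splitlines()
        ref = float(out[1].split("\t")[2])
        assert jaccard_index(a, b) == pytest.approx(ref, abs=1e-9)


class TestShuffle:
    def test_forced_placement_single_valid_start(self):
        layout = GenomeLayout([("chr1", 100)])
        iset = IntervalSet([GenomicInterval("chr1", 0, 100)])
        out = shuffle_intervals(iset, layout, rng_seed=1)
        assert (out[0].start, out[0].end) == (0, 100)

    def test_length_multiset_conserved(self, rng):
        layout = random_layout(rng, 8000)
        iset = random_intervals(rng, layout, n_max=30)
        out = shuffle_intervals(iset, layout, rng_seed=7)
        assert sorted(len(iv) for iv in out) == sorted(len(iv) for iv in iset)

    def test_too_long_interval_rejected(self):
        layout = GenomeLayout([("chr1", 100)])
        with pytest.raises(ValueError):
            shuffle_intervals(
                IntervalSet([GenomicInterval("chr1", 0, 100)]),
                GenomeLayout([("chr1", 50)]),
                rng_seed=1,
            )

    def test_same_chrom_flag(self, rng):
        layout = GenomeLayout([("chr1", 5000), ("chr2", 5000)])
        iset = IntervalSet([GenomicInterval("chr2", 0, 100)] * 20)
        out = shuffle_intervals(iset, layout, rng_seed=3, same_chrom=True)
        assert all(iv.chrom == "chr2" for iv in out)

    def test_blacklist_never_overlapped(self):
        layout = GenomeLayout([("chr1", 1000)]).with_blacklist(
            IntervalSet([GenomicInterval("chr1", 400, 600)])
        )
        iset = IntervalSet([GenomicInterval("chr1", 0, 50)] * 40)
        for seed in range(5):
            out = shuffle_intervals(iset, layout, rng_seed=seed)
            for iv in out:
                assert iv.end <= 400 or iv.start >= 600

    def test_reproducible_given_seed(self, rng):
        layout = random_layout(rng, 5000)
        iset = random_intervals(rng, layout, n_max=20)
        a = shuffle_intervals(iset, layout, rng_seed=99)
        b = shuffle_intervals(iset, layout, rng_seed=99)
        assert a.intervals == b.intervals


class TestPermutationColocalization:
    def test_identical_sparse_sets_minimal_p(self):
        layout = GenomeLayout([("chr1", 100_000)])
        a = IntervalSet(
            [GenomicInterval("chr1", i * 10_000, i * 10_000 + 50) for i in range(5)]
        )
        res = permutation_colocalization(a, a, layout, n_shuffles=199, rng_seed=2)
        assert res.observed == 1.0
        assert res.empirical_p == pytest.approx(1 / 200)
        assert (res.null_values < 1.0).all()
        assert res.z_score > 5

    def test_add_one_estimator_single_shuffle(self):
        layout = GenomeLayout([("chr1", 100_000)])
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        res = permutation_colocalization(a, a, layout, n_shuffles=1, rng_seed=3)
        assert res.empirical_p in (0.5, 1.0)  # (1+0)/2 or (1+1)/2
        if res.null_values[0] < res.observed:
            assert res.empirical_p == 0.5

    def test_contamination_monotonicity(self, rng):
        """Mixing a growing fraction of set A into set B raises the observed
        Jaccard and drives the permutation p below 0.05 at half mixing."""
        layout = GenomeLayout([("chr1", 500_000)])
        a_ivs = [
            GenomicInterval("chr1", int(p), int(p) + 200)
            for p in rng.choice(499_000, 40, replace=False)
        ]
        b_rand = [
            GenomicInterval("chr1", int(p), int(p) + 200)
            for p in rng.choice(499_000, 40, replace=False)
        ]
        observed = []
        for f in (0.0, 0.25, 0.5, 1.0):
            k = int(f * 40)
            b = IntervalSet(a_ivs[:k] + b_rand[k:])
            res = permutation_colocalization(
                IntervalSet(a_ivs), b, layout, n_shuffles=99, rng_seed=11
            )
            observed.append(res.observed)
            if f >= 0.5:
                assert res.empirical_p <= 0.05
        assert observed == sorted(observed)


class TestClassifyTssProximity:
    def _genes(self):
        return GeneTable(
            pd.DataFrame(
                [
                    {"gene_id": "g1", "chrom": "chr1", "tss": 50_000,
                     "strand": "+", "expression": 1.0}
                ]
            )
        )

    @pytest.mark.parametrize(
        "mid, cls",
        [
            (50_000, "proximal"),
            (53_000, "proximal"),
            (53_001, "excluded"),
            (55_000, "excluded"),
            (60_000, "excluded"),
            (60_001, "distal"),
        ],
    )
    def test_threshold_boundaries(self, mid, cls):
        layout = GenomeLayout([("chr1", 200_000)])
        peaks = IntervalSet([GenomicInterval("chr1", mid - 10, mid + 10)])
        parts = classify_tss_proximity(peaks, self._genes())
        assert len(parts[cls]) == 1
        others = set(parts) - {cls}
        assert all(len(parts[o]) == 0 for o in others)

    def test_partition_exhaustive_disjoint(self, rng):
        layout = GenomeLayout([("chr1", 200_000)])
        peaks = random_intervals(rng, layout, n_max=40)
        parts = classify_tss_proximity(peaks, self._genes())
        assert sum(len(p) for p in parts.values()) == len(peaks)
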