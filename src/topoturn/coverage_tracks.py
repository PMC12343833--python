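"""Binned genome coverage tracks: construction, normalization, comparison.

A :class:`CoverageTrack` is the in-memory analog of a bedGraph/bigWig: one
float array per chromosome at a fixed bin width, tagged with a
``normalization_state`` so that the documented pipeline order (spike-scale
each library, combine replicates, then take the log2 ratio) is enforced by
type rather than by convention. Missing data (possible only in
``log2_ratio`` tracks, where both inputs were zero) is stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .genomic_io import (
    FragmentSet,
    GenomeLayout,
    IntervalSet,
    read_bedgraph,
    write_bedgraph,
)

NormState = Literal["raw", "spike_scaled", "znormalized", "log2_ratio"]

#: default scaling constant for spike-in normalization; cancels in every
#: ratio and correlation statistic downstream.
DEFAULT_SCALE_CONSTANT = 10_000.0

#: default pseudocount for log2 ratio tracks.
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CoverageTrack:
    """Fixed-bin-width numeric signal over a genome.

    ``values[chrom]`` has ``ceil(chrom_length / bin_size)`` entries; the last
    bin may cover fewer than ``bin_size`` bases.
    """

    layout: GenomeLayout
    bin_size: int
    values: dict[str, np.ndarray]
    normalization_state: NormState = "raw"
    label: str = ""

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, clen in self.layout.chromosomes:
            expect = -(-clen // self.bin_size)
            got = len(self.values[chrom])
            if got != expect:
                raise ValueError(
                    f"{chrom}: expected {expect} bins, got {got}"
                )

    def all_values(self) -> np.ndarray:
        """All bin values concatenated in layout chromosome order."""
        return np.concatenate(
            [self.values[c] for c, _ in self.layout.chromosomes]
        )

    def defined_values(self) -> np.ndarray:
        vals = self.all_values()
        return vals[~np.isnan(vals)]

    def bin_widths(self, chrom: str) -> np.ndarray:
        """Per-bin widths in bp (last bin may be short)."""
        clen = self.layout.length_of(chrom)
        n = len(self.values[chrom])
        edges = np.minimum(np.arange(n + 1) * self.bin_size, clen)
        return np.diff(edges)

    def copy_with(self, values: dict[str, np.ndarray], state: NormState,
                  label: str | None = None) -> "CoverageTrack":
        return CoverageTrack(
            self.layout, self.bin_size, values, state,
            self.label if label is None else label,
        )

    def to_bedgraph(self, path: str | Path) -> None:
        write_bedgraph(self.values, self.bin_size, self.layout, path)

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        layout: GenomeLayout,
        bin_size: int,
        normalization_state: NormState = "raw",
        missing_as_zero: bool = True,
    ) -> "CoverageTrack":
        vals = read_bedgraph(path, layout, bin_size)
        if missing_as_zero and normalization_state != "log2_ratio":
            vals = {c: np.nan_to_num(v, nan=0.0) for c, v in vals.items()}
        return cls(layout, bin_size, vals, normalization_state)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def coverage_from_fragments(
    frags: FragmentSet, layout: GenomeLayout, bin_size: int
) -> CoverageTrack:
    """Mean per-base fragment depth per bin.

    Bin value = (fragment base pairs falling in the bin) / bin_size, so a bin
    fully covered by one fragment reads 1.0. Computed exactly via a per-base
    difference array and prefix sums.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    values: dict[str, np.ndarray] = {}
    starts_by: dict[str, list[int]] = {c: [] for c, _ in layout.chromosomes}
    ends_by: dict[str, list[int]] = {c: [] for c, _ in layout.chromosomes}
    for iv in frags.fragments:
        layout.check_interval(iv)
        starts_by[iv.chrom].append(iv.start)
        ends_by[iv.chrom].append(iv.end)
    for chrom, clen in layout.chromosomes:
        nbins = -(-clen // bin_size)
        diff = np.zeros(clen + 1)
        s = np.asarray(starts_by[chrom], dtype=np.int64)
        e = np.asarray(ends_by[chrom], dtype=np.int64)
        np.add.at(diff, s, 1.0)
        np.add.at(diff, e, -1.0)
        depth = np.cumsum(diff[:-1])
        # sum per-base depth within each bin, then divide by full bin_size
        idx = np.arange(0, clen, bin_size)
        sums = np.add.reduceat(depth, idx)
        values[chrom] = sums / bin_size
        assert len(values[chrom]) == nbins
    return CoverageTrack(layout, bin_size, values, "raw", frags.library_label)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def spike_in_scale(
    track: CoverageTrack,
    spike_in_count: int,
    scale_constant: float = DEFAULT_SCALE_CONSTANT,
) -> CoverageTrack:
    """Scale a raw track by ``scale_constant / spike_in_count``.

    The exogenous spike-in count is proportional to sequencing depth for a
    fixed spike-in input, so this makes libraries of different depth
    comparable on a common scale.
    """
    if track.normalization_state != "raw":
        raise ValueError(
            f"spike_in_scale expects a raw track, got {track.normalization_state}"
        )
    if spike_in_count <= 0:
        raise ValueError("spike-in normalization undefined for spike_in_count <= 0")
    factor = scale_constant / spike_in_count
    vals = {c: v * factor for c, v in track.values.items()}
    return track.copy_with(vals, "spike_scaled")


def znormalize_track(track: CoverageTrack) -> CoverageTrack:
    """Transform every defined bin to (value - mean) / SD (population SD).

    The resulting track has mean 0 and SD 1 over its defined bins. Constant
    tracks (SD = 0) are rejected.
    """
    vals = track.defined_values()
    if vals.size == 0:
        raise ValueError("cannot z-normalize an all-missing track")
    mean = float(np.mean(vals))
    sd = float(np.std(vals))  # population SD
    if sd == 0.0:
        raise ValueError("cannot z-normalize a constant track (SD = 0)")
    out = {c: (v - mean) / sd for c, v in track.values.items()}
    return track.copy_with(out, "znormalized")


def combine_replicates(
    inputs: Sequence[CoverageTrack] | Sequence[FragmentSet],
    mode: Literal["average_tracks", "merge_fragments"],
) -> CoverageTrack | FragmentSet:
    """Average replicate tracks bin-wise, or pool replicate fragment sets.

    ``average_tracks`` is the bigwigAverage analog (requires matching layout,
    bin size and normalization state); ``merge_fragments`` concatenates
    fragments and sums spike-in counts, the samtools-merge analog used to
    increase read depth before a single track is built.
    """
    if len(inputs) < 2:
        raise ValueError("need at least 2 replicates to combine")
    if mode == "average_tracks":
        tracks = list(inputs)
        first = tracks[0]
        if not all(isinstance(t, CoverageTrack) for t in tracks):
            raise TypeError("average_tracks expects CoverageTracks")
        for t in tracks[1:]:
            if t.layout.chromosomes != first.layout.chromosomes:
                raise ValueError("replicate tracks have mismatched layouts")
            if t.bin_size != first.bin_size:
                raise ValueError("replicate tracks have mismatched bin sizes")
            if t.normalization_state != first.normalization_state:
                raise ValueError(
                    "replicate tracks must share a normalization state; "
                    "scale before averaging"
                )
        vals = {
            c: np.mean([t.values[c] for t in tracks], axis=0)
            for c, _ in first.layout.chromosomes
        }
        return first.copy_with(vals, first.normalization_state, label="avg")
    elif mode == "merge_fragments":
        fsets = list(inputs)
        if not all(isinstance(f, FragmentSet) for f in fsets):
            raise TypeError("merge_fragments expects FragmentSets")
        merged = [iv for f in fsets for iv in f.fragments]
        spike = sum(f.spike_in_count for f in fsets)
        label = "+".join(f.library_label for f in fsets if f.library_label)
        return FragmentSet(IntervalSet(merged, label="merged"), spike, label)
    raise ValueError(f"unknown mode {mode!r}")


def log2_ratio_track(
    numerator: CoverageTrack,
    denominator: CoverageTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CoverageTrack:
    """Per-bin log2((num + pc) / (den + pc)); the ΔTOP1cc construction.

    Bins where both inputs are exactly zero carry no evidence either way and
    are masked (NaN) rather than reported as 0. Inputs must share layout, bin
    size and normalization state.
    """
    if numerator.layout.chromosomes != denominator.layout.chromosomes:
        raise ValueError("layout mismatch")
    if numerator.bin_size != denominator.bin_size:
        raise ValueError("bin size mismatch")
    if numerator.normalization_state != denominator.normalization_state:
        raise ValueError(
            "normalization state mismatch: "
            f"{numerator.normalization_state} vs {denominator.normalization_state}"
        )
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    vals: dict[str, np.ndarray] = {}
    for c, _ in numerator.layout.chromosomes:
        num = numerator.values[c]
        den = denominator.values[c]
        out = np.log2((num + pseudocount) / (den + pseudocount))
        out[(num == 0) & (den == 0)] = np.nan
        out[np.isnan(num) | np.isnan(den)] = np.nan
        vals[c] = out
    return numerator.copy_with(vals, "log2_ratio", label="log2_ratio")


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def _region_means(track: CoverageTrack, regions: IntervalSet) -> np.ndarray:
    # local import: metaprofile depends on this module
    from .metaprofile import region_mean_signal

    return region_mean_signal(track, regions)


def binned_correlation(
    tracks: Sequence[CoverageTrack],
    regions: IntervalSet | None = None,
    bin_size: int = 10_000,
    method: Literal["spearman", "pearson"] = "spearman",
) -> np.ndarray:
    """Pairwise correlation of tracks over equal-size bins or given regions.

    With no ``regions``, each track is summarized as its mean signal over a
    genome-wide tiling of ``bin_size`` windows (10 kb by default); with
    ``regions``, one averaged score per region is used instead. Bins where
    any pair member is undefined are dropped pairwise-complete. Returns a
    symmetric matrix with unit diagonal.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    layout = tracks[0].layout
    for t in tracks[1:]:
        if t.layout.chromosomes != layout.chromosomes:
            raise ValueError("tracks have mismatched layouts")
    if regions is None:
        from .genomic_io import GenomicInterval

        tiling = []
        for chrom, clen in layout.chromosomes:
            for start in range(0, clen, bin_size):
                tiling.append(
                    GenomicInterval(chrom, start, min(start + bin_size, clen))
                )
        regions = IntervalSet(tiling, label="tiling")
    scores = np.vstack([_region_means(t, regions) for t in tracks])
    k = len(tracks)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(scores[i]) & ~np.isnan(scores[j])
            if ok.sum() < 2:
                raise ValueError("fewer than 2 usable bins for correlation")
            if method == "spearman":
                r = _scipy_stats.spearmanr(scores[i][ok], scores[j][ok]).statistic
            elif method == "pearson":
                r = _scipy_stats.pearsonr(scores[i][ok], scores[j][ok]).statistic
            else:
                raise ValueError(f"unknown method {method!r}")
            mat[i, j] = mat[j, i] = r
    return mat
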