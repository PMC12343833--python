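"""Reference-point signal matrices, averaged profiles, and LOESS smoothing.

The computeMatrix/plotProfile analog: extract strand-oriented signal windows
around anchor points (typically TSS or peak centers), average them
column-wise, and optionally smooth the averaged profile with local linear
regression (tricube weights).

Missing data convention: windows extending past chromosome ends, and masked
track bins, are NaN and are *excluded* from means — never zero-filled, which
would fabricate signal depletion at chromosome boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .coverage_tracks import CoverageTrack
from .genomic_io import GenomeLayout, IntervalSet

#: LOESS span used for peak-centered average profiles.
DEFAULT_SPAN = 0.15
#: finer span for high-resolution TSS profiles.
FINE_SPAN = 0.025


@dataclass(frozen=True)
class Anchor:
    chrom: str
    position: int
    strand: str = "."


@dataclass
class AnchorSet:
    """Oriented reference points (e.g. TSS, peak midpoints)."""

    points: list[Anchor]
    label: str = ""

    def __len__(self) -> int:
        return len(self.points)

    def validate(self, layout: GenomeLayout) -> None:
        for a in self.points:
            if a.chrom not in layout:
                raise ValueError(f"anchor on unknown chromosome {a.chrom!r}")
            if not (0 <= a.position < layout.length_of(a.chrom)):
                raise ValueError(
                    f"anchor position {a.position} outside {a.chrom}"
                )

    @classmethod
    def from_intervals(
        cls, iset: IntervalSet, use_strand: bool = True
    ) -> "AnchorSet":
        """Midpoint anchors from an interval set."""
        pts = [
            Anchor(iv.chrom, iv.midpoint, iv.strand if use_strand else ".")
            for iv in iset
        ]
        return cls(pts, label=iset.label)


@dataclass
class SignalMatrix:
    """Anchors x positional-bins matrix of track signal.

    Rows follow the AnchorSet order; columns span [-upstream, +downstream)
    at ``bin_width`` resolution. Minus-strand rows are flipped at
    construction so column 0 is always the 5'-most position relative to the
    anchor. NaN marks off-chromosome padding or masked track bins.
    """

    values: np.ndarray  # (n_anchors, n_cols)
    upstream: int
    downstream: int
    bin_width: int
    track_label: str = ""
    anchor_label: str = ""

    @property
    def n_cols(self) -> int:
        return (self.upstream + self.downstream) // self.bin_width

    @property
    def positions(self) -> np.ndarray:
        """Center of each positional bin relative to the anchor (bp)."""
        return (
            np.arange(self.n_cols) * self.bin_width
            - self.upstream
            + self.bin_width / 2
        )

    def to_tsv(self, path: str | Path) -> None:
        header = json.dumps(
            {
                "upstream": self.upstream,
                "downstream": self.downstream,
                "bin_width": self.bin_width,
                "track": self.track_label,
                "anchors": self.anchor_label,
            }
        )
        with open(path, "w") as fh:
            fh.write("#" + header + "\n")
            np.savetxt(fh, self.values, fmt="%.6g", delimiter="\t")


def compute_matrix(
    track: CoverageTrack,
    anchors: AnchorSet,
    upstream: int,
    downstream: int,
    bin_width: int,
) -> SignalMatrix:
    """Signal around each anchor, strand-oriented.

    Each cell is the mean track value over its positional window (bp-weighted
    over track bins). ``bin_width`` must divide both flanks and be a multiple
    of the track's bin size so cells tile track bins exactly after alignment
    to the anchor.
    """
    if upstream % bin_width or downstream % bin_width:
        raise ValueError("bin_width must divide upstream and downstream")
    if bin_width % track.bin_size:
        raise ValueError("bin_width must be a multiple of the track bin size")
    n_cols = (upstream + downstream) // bin_width
    layout = track.layout
    anchors.validate(layout)
    out = np.full((len(anchors), n_cols), np.nan)
    span = upstream + downstream
    for r, a in enumerate(anchors.points):
        clen = layout.length_of(a.chrom)
        if a.strand == "-":
            w_start, w_end = a.position - downstream, a.position + upstream
        else:
            w_start, w_end = a.position - upstream, a.position + downstream
        # per-base values over the window, NaN outside the chromosome
        base = np.full(span, np.nan)
        lo, hi = max(w_start, 0), min(w_end, clen)
        if hi > lo:
            tv = track.values[a.chrom]
            bidx = np.arange(lo, hi) // track.bin_size
            base[lo - w_start : hi - w_start] = tv[bidx]
        if a.strand == "-":
            base = base[::-1]
        cells = base.reshape(n_cols, bin_width)
        with np.errstate(invalid="ignore"):
            counts = np.sum(~np.isnan(cells), axis=1)
            sums = np.nansum(cells, axis=1)
        row = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[r] = row
    return SignalMatrix(
        out, upstream, downstream, bin_width,
        track_label=track.label, anchor_label=anchors.label,
    )


def loess_smooth(y: np.ndarray, span: float) -> np.ndarray:
    """Degree-1 LOESS over index positions with tricube weights.

    Window = nearest ceil(span * n) points, no robustness iterations. NaN
    entries are dropped from the fit and returned as NaN.
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    y = np.asarray(y, dtype=float)
    x = np.arange(len(y), dtype=float)
    ok = ~np.isnan(y)
    if ok.sum() < 2:
        return y.copy()
    frac = min(1.0, np.ceil(span * ok.sum()) / ok.sum())
    sm = _sm_lowess(
        y[ok], x[ok], frac=frac, it=0, xvals=x[ok], is_sorted=True
    )
    out = np.full_like(y, np.nan)
    out[ok] = sm
    return out


def mean_profile(
    matrix: SignalMatrix, smoothing_span: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mean over non-missing cells, optionally LOESS-smoothed.

    Returns ``(profile, n_per_column)``; columns with zero non-missing cells
    are NaN with n 0, and stay NaN after smoothing.
    """
    if matrix.values.size == 0:
        raise ValueError("empty signal matrix")
    with np.errstate(invalid="ignore"):
        n = np.sum(~np.isnan(matrix.values), axis=0)
        sums = np.nansum(matrix.values, axis=0)
    prof = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    if smoothing_span is not None:
        prof = loess_smooth(prof, smoothing_span)
    return prof, n


def region_mean_signal(
    track: CoverageTrack, windows: IntervalSet
) -> np.ndarray:
    """Mean track value over each window, bp-weighted across partial bins.

    Missing (NaN) bins contribute neither signal nor weight; a window whose
    bins are all missing yields NaN.
    """
    out = np.full(len(windows), np.nan)
    bs = track.bin_size
    for i, iv in enumerate(windows):
        track.layout.check_interval(iv)
        tv = track.values[iv.chrom]
        b0, b1 = iv.start // bs, -(-iv.end // bs)
        vals = tv[b0:b1]
        # bp overlap of the window with each touched bin
        edges_lo = np.maximum(np.arange(b0, b1) * bs, iv.start)
        edges_hi = np.minimum((np.arange(b0, b1) + 1) * bs, iv.end)
        w = (edges_hi - edges_lo).astype(float)
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        out[i] = np.sum(vals[ok] * w[ok]) / np.sum(w[ok])
    return out


def write_profile_tsv(
    positions: np.ndarray, profile: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("position\tsignal\n")
        for p, v in zip(positions, profile):
            fh.write(f"{p:g}\t{'NA' if np.isnan(v) else format(v, '.6g')}\n")
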