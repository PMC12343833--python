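"""ΔTOP1cc stratified statistics.

The turnover statistic ΔTOP1cc is the per-bin log2 ratio of TOP1cc coverage
after prolonged camptothecin damage (30' CPT) over steady state (5' CPT);
values above 0 indicate damage-induced TOP1cc accumulation, i.e. impaired
clearance. This module stratifies per-gene ΔTOP1cc (mean over TSS +/- 250 bp
by default) by RNA-seq expression quartile, stratifies TOP1 peaks by
macroH2A1.1 occupancy tertile, and attaches two-sided Mann-Whitney U tests
to the pairwise group contrasts.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coverage_tracks import CoverageTrack
from .genomic_io import GenomeLayout, GenomicInterval, IntervalSet
from .metaprofile import region_mean_signal

logger = logging.getLogger("topoturn")

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")

#: half-width of the TSS window over which ΔTOP1cc is averaged per gene.
DEFAULT_WINDOW_HALFWIDTH = 250

#: sample-size bound below which the Mann-Whitney p value is computed by
#: exact enumeration (when the pooled sample has no ties).
EXACT_ENUMERATION_MAX_N = 12


@dataclass
class GeneTable:
    """Per-gene TSS anchors with expression values and quartile labels.

    Backed by a DataFrame with columns ``gene_id, chrom, tss, strand,
    expression`` plus ``quartile`` once assigned.
    """

    df: pd.DataFrame

    REQUIRED = ("gene_id", "chrom", "tss", "strand", "expression")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"gene table missing columns {missing}")
        expr = self.df["expression"].to_numpy(dtype=float)
        if not np.all(np.isfinite(expr)):
            raise ValueError("expression values must be finite")
        if (expr < 0).any():
            raise ValueError("expression values must be non-negative")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def tss_windows(
        self, layout: GenomeLayout, halfwidth: int
    ) -> IntervalSet:
        """TSS +/- halfwidth windows, clipped to chromosome bounds."""
        ivs = []
        for row in self.df.itertuples():
            clen = layout.length_of(row.chrom)
            start = max(0, row.tss - halfwidth)
            end = min(clen, row.tss + halfwidth)
            ivs.append(GenomicInterval(row.chrom, start, end, row.strand))
        return IntervalSet(ivs, label="tss_windows")


@dataclass
class StratifiedResult:
    """Group-wise per-region statistics with pairwise rank tests."""

    groups: dict[str, np.ndarray]
    pairwise_tests: dict[tuple[str, str], dict[str, float]]
    n_excluded: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, vals in self.groups.items():
            rows.append(
                {
                    "group": label,
                    "n": len(vals),
                    "median": float(np.median(vals)) if len(vals) else np.nan,
                    "q25": float(np.percentile(vals, 25)) if len(vals) else np.nan,
                    "q75": float(np.percentile(vals, 75)) if len(vals) else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def medians(self) -> dict[str, float]:
        return {
            k: float(np.median(v)) if len(v) else float("nan")
            for k, v in self.groups.items()
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "groups": {
                k: {"n": len(v), "median": float(np.median(v)) if len(v) else None}
                for k, v in self.groups.items()
            },
            "pairwise_tests": {
                f"{a}_vs_{b}": t for (a, b), t in self.pairwise_tests.items()
            },
            "n_excluded": self.n_excluded,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a_i, b_j) pairs with a_i > b_j, ties 1/2."""
    gt = np.sum(a[:, None] > b[None, :])
    eq = np.sum(a[:, None] == b[None, :])
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float]
) -> dict[str, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of all C(n1+n2, n1) labelings when the
    pooled sample has at most :data:`EXACT_ENUMERATION_MAX_N` observations
    and no ties; otherwise the normal approximation with tie correction and
    a 0.5 continuity correction. Returns ``{"U": ..., "p": ..., "method": ...}``
    with U the statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size

    if n1 + n2 <= EXACT_ENUMERATION_MAX_N and no_ties:
        # enumerate every assignment of pooled values to the first sample
        mu = n1 * n2 / 2.0
        d_obs = abs(u_obs - mu)
        total = comb(n1 + n2, n1)
        hits = 0
        idx = range(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mu) >= d_obs - 1e-12:
                hits += 1
        return {"U": u_obs, "p": hits / total, "method": "exact"}

    # normal approximation with tie correction + continuity correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return {"U": u_obs, "p": 1.0, "method": "asymptotic"}
    z = max(0.0, abs(u_obs - mu) - 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(z))
    return {"U": u_obs, "p": p, "method": "asymptotic"}


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def assign_expression_quartiles(genes: GeneTable) -> GeneTable:
    """Rank genes by expression and split ranks into Q1..Q4, sizes +/- 1.

    Rank ties are broken by stable input (gene-id table) order, so the
    assignment is deterministic even for degenerate expression vectors.
    Q1 is the bottom 25%, Q4 the top 25%.
    """
    df = genes.df.copy()
    if len(df) < 4:
        raise ValueError("need at least 4 genes for quartile assignment")
    order = np.argsort(df["expression"].to_numpy(), kind="stable")
    labels = np.empty(len(df), dtype=object)
    for q, chunk in zip(QUARTILE_LABELS, np.array_split(order, 4)):
        labels[chunk] = q
    df["quartile"] = labels
    return GeneTable(df)


def delta_by_group(
    delta_track: CoverageTrack,
    genes: GeneTable,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> StratifiedResult:
    """Per-gene mean ΔTOP1cc over TSS windows, grouped by expression quartile.

    Genes whose window is entirely missing in the ratio track (no coverage in
    either condition) are excluded and counted. All 6 pairwise two-sided
    Mann-Whitney U tests between quartiles are reported, unadjusted, mirroring
    how raw pairwise p values are conventionally reported for this contrast;
    apply :func:`benjamini_hochberg` to the result if adjustment is wanted.
    """
    if delta_track.normalization_state != "log2_ratio":
        raise ValueError("delta_by_group expects a log2_ratio track")
    if "quartile" not in genes.df.columns:
        raise ValueError("assign_expression_quartiles first")
    windows = genes.tss_windows(delta_track.layout, window_halfwidth)
    vals = region_mean_signal(delta_track, windows)
    quartiles = genes.df["quartile"].to_numpy()
    groups: dict[str, np.ndarray] = {}
    n_excluded = int(np.isnan(vals).sum())
    if n_excluded:
        logger.info(
            "delta_by_group: excluded %d genes with fully-missing windows",
            n_excluded,
        )
    for q in QUARTILE_LABELS:
        sel = (quartiles == q) & ~np.isnan(vals)
        groups[q] = vals[sel]
    tests: dict[tuple[str, str], dict[str, float]] = {}
    for qa, qb in itertools.combinations(QUARTILE_LABELS, 2):
        if len(groups[qa]) and len(groups[qb]):
            tests[(qa, qb)] = mann_whitney_u(groups[qa], groups[qb])
    return StratifiedResult(groups, tests, n_excluded)


def benjamini_hochberg(result: StratifiedResult) -> StratifiedResult:
    """Return a copy with BH-adjusted p values added to each pairwise test."""
    from statsmodels.stats.multitest import multipletests

    keys = list(result.pairwise_tests)
    pvals = [result.pairwise_tests[k]["p"] for k in keys]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    tests = {
        k: {**result.pairwise_tests[k], "p_adjusted": float(q)}
        for k, q in zip(keys, adj)
    }
    return StratifiedResult(result.groups, tests, result.n_excluded)


def stratify_by_signal_tertiles(
    peaks: IntervalSet,
    occupancy_track: CoverageTrack,
    score: str = "mean",
) -> tuple[IntervalSet, IntervalSet]:
    """Split peaks into top/bottom occupancy tertiles; middle discarded.

    Each peak is scored by its mean (or max, ``score="max"``) occupancy
    signal; ties are broken by stable input order. Returns
    ``(high, low)``.
    """
    if len(peaks) < 3:
        raise ValueError("need at least 3 peaks for tertile stratification")
    if score == "mean":
        vals = region_mean_signal(occupancy_track, peaks)
    elif score == "max":
        vals = np.array(
            [
                np.nanmax(
                    occupancy_track.values[iv.chrom][
                        iv.start // occupancy_track.bin_size : -(
                            -iv.end // occupancy_track.bin_size
                        )
                    ]
                )
                for iv in peaks
            ]
        )
    else:
        raise ValueError(f"unknown score {score!r}")
    if np.unique(vals[~np.isnan(vals)]).size <= 1:
        warnings.warn(
            "all peak occupancy scores equal; tertile split falls back to "
            "stable input order",
            stacklevel=2,
        )
    order = np.argsort(np.nan_to_num(vals, nan=-np.inf), kind="stable")
    parts = np.array_split(order, 3)
    low_idx, high_idx = sorted(parts[0]), sorted(parts[2])
    high = IntervalSet([peaks[i] for i in high_idx], label=f"{peaks.label}_high")
    low = IntervalSet([peaks[i] for i in low_idx], label=f"{peaks.label}_low")
    return high, low
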