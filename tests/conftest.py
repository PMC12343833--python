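"""Shared fixtures and per-base brute-force oracles.

The oracles deliberately work on explicit per-base boolean/float arrays over
small (<= 10 kb) genomes, independent of the interval sweeps and binned
arithmetic used by the package itself.
"""

from __future__ import annotations

import numpy as np
import pytest

from topoturn import (
    FragmentSet,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
)


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    return GenomeLayout([("chr1", 1000), ("chr2", 500)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# random fixture generators
# ---------------------------------------------------------------------------

def random_layout(rng: np.random.Generator, max_len: int = 10_000) -> GenomeLayout:
    n = int(rng.integers(1, 4))
    chroms = [
        (f"chr{i + 1}", int(rng.integers(200, max_len + 1))) for i in range(n)
    ]
    return GenomeLayout(chroms)


def random_intervals(
    rng: np.random.Generator,
    layout: GenomeLayout,
    n_max: int = 20,
    label: str = "rand",
) -> IntervalSet:
    ivs = []
    for _ in range(int(rng.integers(0, n_max + 1))):
        chrom, clen = layout.chromosomes[int(rng.integers(len(layout.chromosomes)))]
        start = int(rng.integers(0, clen))
        end = int(rng.integers(start + 1, min(start + 500, clen) + 1))
        ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivs, label=label)


# ---------------------------------------------------------------------------
# per-base oracles
# ---------------------------------------------------------------------------

def bitmap(iset: IntervalSet, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-base membership arrays."""
    out = {c: np.zeros(l, dtype=bool) for c, l in layout.chromosomes}
    for iv in iset:
        out[iv.chrom][iv.start : iv.end] = True
    return out


def oracle_jaccard(a: IntervalSet, b: IntervalSet, layout: GenomeLayout) -> float:
    ba, bb = bitmap(a, layout), bitmap(b, layout)
    inter = sum(int((ba[c] & bb[c]).sum()) for c, _ in layout.chromosomes)
    union = sum(int((ba[c] | bb[c]).sum()) for c, _ in layout.chromosomes)
    if union == 0:
        raise ValueError("undefined")
    return inter / union


def oracle_depth(frags: IntervalSet, layout: GenomeLayout) -> dict[str, np.ndarray]:
    out = {c: np.zeros(l) for c, l in layout.chromosomes}
    for iv in frags:
        out[iv.chrom][iv.start : iv.end] += 1.0
    return out


def oracle_bin_means(
    depth: dict[str, np.ndarray], layout: GenomeLayout, bin_size: int
) -> dict[str, np.ndarray]:
    out = {}
    for c, clen in layout.chromosomes:
        nbins = -(-clen // bin_size)
        vals = np.zeros(nbins)
        for b in range(nbins):
            vals[b] = depth[c][b * bin_size : (b + 1) * bin_size].sum() / bin_size
        out[c] = vals
    return out


def oracle_overlaps(iv: GenomicInterval, other: IntervalSet) -> bool:
    return any(
        o.chrom == iv.chrom and o.start < iv.end and iv.start < o.end
        for o in other
    )
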