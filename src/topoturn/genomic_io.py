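"""Genomic coordinate types and text-format I/O.

All coordinates are 0-based half-open (BED convention). Any 1-based
presentation is the caller's responsibility; nothing in this package ever
stores 1-based positions.

Formats handled here: two-column chrom.sizes, BED3/BED6, and 4-column
bedGraph. Writers emit tab-delimited, newline-terminated text readable by
standard genome browsers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np

logger = logging.getLogger("topoturn")

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed line in a genomic text file; message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional strand/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class IntervalSet:
    """An ordered collection of intervals sharing one coordinate universe.

    May contain overlapping intervals unless explicitly flattened (see
    :func:`topoturn.colocalization.flatten`).
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def total_bp(self) -> int:
        """Summed interval lengths (double-counts overlaps; flatten first
        for covered bp)."""
        return sum(len(iv) for iv in self.intervals)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
            label=self.label,
        )

    def validate(self, layout: "GenomeLayout") -> None:
        for iv in self.intervals:
            layout.check_interval(iv)


@dataclass
class GenomeLayout:
    """Chromosome names/lengths plus an (optionally empty) blacklist.

    The coordinate universe every other object is validated against.
    """

    chromosomes: list[tuple[str, int]]
    blacklist: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self._lengths = dict(self.chromosomes)
        self.blacklist.validate(self)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def check_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._lengths:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > self._lengths[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                f"chromosome end ({self._lengths[iv.chrom]})"
            )

    def with_blacklist(self, blacklist: IntervalSet) -> "GenomeLayout":
        return GenomeLayout(list(self.chromosomes), blacklist)


@dataclass
class FragmentSet:
    """Simulated aligned fragments for one library.

    ``spike_in_count`` is the number of fragments attributed to the exogenous
    spike-in genome; those fragments are not represented individually, only
    counted, since only the count enters normalization.
    """

    fragments: IntervalSet
    spike_in_count: int = 0
    library_label: str = ""

    def __post_init__(self) -> None:
        if self.spike_in_count < 0:
            raise ValueError("spike_in_count must be >= 0")

    def __len__(self) -> int:
        return len(self.fragments)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Parse a two-column (name, length) chrom.sizes file.

    Line order is preserved; the returned layout has an empty blacklist.
    """
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        name, length_s = parts
        try:
            length = int(length_s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer length {length_s!r}") from None
        if length <= 0:
            raise ParseError(f"{path}:{lineno}: non-positive length for {name}")
        if name in seen:
            raise ParseError(f"{path}:{lineno}: duplicate chromosome {name}")
        seen.add(name)
        chroms.append((name, length))
    if not chroms:
        raise ParseError(f"{path}: no chromosomes found")
    return GenomeLayout(chroms)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


def parse_bed(
    path: str | Path,
    layout: GenomeLayout,
    label: str = "",
    strict: bool = True,
) -> IntervalSet:
    """Parse BED3/BED6 against a layout.

    Strand comes from column 6 when present, score from column 5 when present
    and numeric; extra columns are ignored. Records on chromosomes missing
    from the layout raise in strict mode (default) and are skipped with a
    warning otherwise. Coordinate violations always raise, with line number.
    """
    intervals: list[GenomicInterval] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
        chrom = cols[0]
        if chrom not in layout:
            if strict:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            logger.warning("%s:%d: skipping unknown chromosome %r", path, lineno, chrom)
            continue
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if not (0 <= start < end):
            raise ParseError(f"{path}:{lineno}: require 0 <= start < end")
        if end > layout.length_of(chrom):
            raise ParseError(
                f"{path}:{lineno}: end {end} beyond chromosome length "
                f"{layout.length_of(chrom)}"
            )
        score: float | None = None
        if len(cols) >= 5 and cols[4] not in (".", ""):
            try:
                score = float(cols[4])
            except ValueError:
                score = None
        strand = "."
        if len(cols) >= 6 and cols[5] in ("+", "-"):
            strand = cols[5]
        intervals.append(GenomicInterval(chrom, start, end, strand, score))
    return IntervalSet(intervals, label=label or Path(path).stem)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED6 when any interval carries strand/score, else BED3."""
    bed6 = any(iv.strand != "." or iv.score is not None for iv in iset)
    with open(path, "w") as fh:
        for i, iv in enumerate(iset):
            if bed6:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iset.label or 'iv'}_{i}"
                    f"\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# blacklist filtering
# ---------------------------------------------------------------------------

def _overlaps_any(
    iv: GenomicInterval, by_chrom: dict[str, np.ndarray]
) -> bool:
    arr = by_chrom.get(iv.chrom)
    if arr is None or arr.size == 0:
        return False
    starts, ends = arr[:, 0], arr[:, 1]
    return bool(np.any((starts < iv.end) & (iv.start < ends)))


def apply_blacklist(
    records: Union[FragmentSet, IntervalSet], layout: GenomeLayout
) -> Union[FragmentSet, IntervalSet]:
    """Drop every record overlapping the layout's blacklist by >= 1 bp.

    Half-open convention: abutting records (record.end == blacklist.start)
    are retained. Input order is preserved; a FragmentSet keeps its spike-in
    count. With an empty blacklist this is the identity.
    """
    if isinstance(records, FragmentSet):
        kept = apply_blacklist(records.fragments, layout)
        assert isinstance(kept, IntervalSet)
        return FragmentSet(kept, records.spike_in_count, records.library_label)

    if len(layout.blacklist) == 0:
        return IntervalSet(list(records.intervals), label=records.label)
    by_chrom: dict[str, np.ndarray] = {}
    for iv in layout.blacklist:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))  # type: ignore[attr-defined]
    by_chrom = {c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()}
    kept_ivs = [iv for iv in records if not _overlaps_any(iv, by_chrom)]
    return IntervalSet(kept_ivs, label=records.label)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(
    values_by_chrom: dict[str, np.ndarray],
    bin_size: int,
    layout: GenomeLayout,
    path: str | Path,
) -> None:
    """Serialize per-bin values as 4-column bedGraph.

    Runs of equal value are collapsed into single lines; NaN (missing) bins
    are omitted. Output is sorted by layout chromosome order then start, with
    no overlapping lines.
    """
    with open(path, "w") as fh:
        for chrom, clen in layout.chromosomes:
            vals = values_by_chrom[chrom]
            n = len(vals)
            edges = np.minimum(np.arange(n + 1) * bin_size, clen)
            # run-length encode equal consecutive values (NaN == NaN here)
            same = np.zeros(n, dtype=bool)
            if n > 1:
                a, b = vals[1:], vals[:-1]
                same[1:] = (a == b) | (np.isnan(a) & np.isnan(b))
            run_starts = np.flatnonzero(~same)
            run_ends = np.append(run_starts[1:], n)
            for rs, re in zip(run_starts, run_ends):
                v = vals[rs]
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{edges[rs]}\t{edges[re]}\t{v:.6g}\n")


def read_bedgraph(
    path: str | Path, layout: GenomeLayout, bin_size: int
) -> dict[str, np.ndarray]:
    """Read a bedGraph whose lines align to a fixed bin grid.

    Bins not covered by any line are NaN (missing). Lines must not overlap
    and must start/end on bin boundaries (or the chromosome end).
    """
    out = {
        chrom: np.full(int(np.ceil(clen / bin_size)), np.nan)
        for chrom, clen in layout.chromosomes
    }
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
        if chrom not in layout:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        clen = layout.length_of(chrom)
        if start % bin_size or (end % bin_size and end != clen):
            raise ParseError(
                f"{path}:{lineno}: interval not aligned to {bin_size}-bp bins"
            )
        b0, b1 = start // bin_size, int(np.ceil(end / bin_size))
        if np.any(~np.isnan(out[chrom][b0:b1])):
            raise ParseError(f"{path}:{lineno}: overlapping bedGraph lines")
        out[chrom][b0:b1] = value
    return out
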