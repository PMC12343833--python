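"""Synthetic genomes, annotations, and fragment libraries with known truth.

Emulates, downstream of alignment, the two assay designs the analysis
consumes:

* **CUT&RUN-like libraries** — fragment midpoints drawn from a uniform
  background mixed with enrichment-fold-weighted placement over a target's
  true intervals (TOP1 hotspots or macroH2A1.1 domains; IgG is pure
  background), plus a binomial exogenous spike-in fragment count.

* **CAD-Seq-like libraries** — per TOP1 hotspot, Poisson fragment counts
  whose intensity under prolonged damage (30' CPT) is amplified relative to
  steady state (5' CPT) by a turnover-deficit term that scales with the
  linked gene's normalized expression and is suppressed by macroH2A1.1
  occupancy in the control genotype:

      intensity_30 = lambda_s * w_h * (1 + delta_g * e_h * (1 - rho * m_h * [g = control]))

  so macroH2A1.1-covered hotspots accumulate nothing in control cells
  (rho = 1) while knockdown cells accumulate in proportion to expression.
  The expected ΔTOP1cc at a hotspot is therefore log2 of that factor,
  independent of lambda_s — the closed form recovery tests check against.

Everything is reproducible bit-for-bit from (scenario, seed) via the Philox
counter-based generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (
    FragmentSet,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
)
from .turnover_stats import GeneTable

CUTRUN_TARGETS = ("TOP1", "macroH2A1.1", "IgG")
CAD_CONDITIONS = ("steady_5min", "prolonged_30min")
GENOTYPES = ("control", "macroH2A1_1_KD")


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


@dataclass
class SimScenario:
    """Parameters of one simulated study.

    Defaults describe a desk-scale genome (4 x 2 Mbp) carrying 400 genes and
    300 TOP1 hotspots (70% TSS-linked), sized so the full analysis pipeline
    runs in minutes on one CPU while every stratified contrast remains
    statistically detectable.
    """

    # genome
    n_chromosomes: int = 4
    chromosome_length: int = 2_000_000
    blacklist_fraction: float = 0.005
    blacklist_interval_bp: int = 2_000
    # genes
    n_genes: int = 400
    expression_log_mean: float = 1.0
    expression_log_sd: float = 1.0
    # TOP1 hotspots
    n_hotspots: int = 300
    hotspot_width_mean: float = 1_000.0
    hotspot_width_sd: float = 200.0
    tss_linked_fraction: float = 0.7
    # macroH2A1.1 domains
    n_domains: int = 200
    domain_width_mean: float = 5_000.0
    domain_width_sd: float = 1_000.0
    domain_hotspot_overlap_fraction: float = 0.5
    # CUT&RUN libraries
    cutrun_fragment_count: int = 100_000
    cutrun_fragment_length_mean: float = 150.0
    cutrun_fragment_length_sd: float = 25.0
    cutrun_enrichment_fold: float = 20.0
    # CAD-Seq libraries (fragments are ~1 kb post-sonication)
    cad_rate_per_bp: float = 0.2
    cad_tss_rate_per_bp: float = 0.05
    cad_tss_halfwidth: int = 500
    cad_background_per_bp: float = 0.001
    cad_fragment_length_mean: float = 1_000.0
    cad_fragment_length_sd: float = 150.0
    # spike-in
    spike_in_fraction: float = 0.05
    # turnover model
    delta_control: float = 3.0
    delta_kd: float = 3.0
    protection_rho: float = 1.0
    # rng
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "blacklist_fraction",
            "tss_linked_fraction",
            "domain_hotspot_overlap_fraction",
            "spike_in_fraction",
            "protection_rho",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cad_rate_per_bp <= 0:
            raise ValueError("cad_rate_per_bp must be > 0")
        if self.delta_control < 0 or self.delta_kd < 0:
            raise ValueError("turnover deficits must be >= 0")
        if self.hotspot_width_mean <= 0 or self.domain_width_mean <= 0:
            raise ValueError("feature widths must be positive")

    def delta_for(self, genotype: str) -> float:
        if genotype == "control":
            return self.delta_control
        if genotype == "macroH2A1_1_KD":
            return self.delta_kd
        raise ValueError(f"unknown genotype {genotype!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class SimTruth:
    """Ground truth of one simulated study: sufficient to recompute every
    expected value used in recovery tests."""

    layout: GenomeLayout
    genes: GeneTable
    hotspots: IntervalSet
    domains: IntervalSet
    # per-hotspot annotations, aligned with `hotspots` order
    hotspot_gene_id: list[str | None]
    hotspot_expression_norm: np.ndarray  # e_h in [0, 1]; 0 for non-TSS hotspots
    hotspot_occupied: np.ndarray  # m_h: domain covers hotspot midpoint
    # per-gene annotations, aligned with `genes` order
    gene_expression_norm: np.ndarray  # e_g = expression / max expression
    gene_occupied: np.ndarray  # m_g: domain covers the TSS
    scenario: SimScenario
    rng_seed: int

    def expected_delta_top1cc(
        self, genotype: str, scenario: "SimScenario | None" = None
    ) -> np.ndarray:
        """Closed-form expected ΔTOP1cc (log2) per hotspot.

        ``scenario`` overrides the truth's own scenario (e.g. to evaluate a
        different turnover deficit on the same genome)."""
        sc = scenario or self.scenario
        delta = sc.delta_for(genotype)
        protected = (
            sc.protection_rho * self.hotspot_occupied
            if genotype == "control"
            else np.zeros(len(self.hotspot_occupied))
        )
        factor = 1.0 + delta * self.hotspot_expression_norm * (1.0 - protected)
        return np.log2(factor)

    def expected_delta_top1cc_tss(
        self, genotype: str, scenario: "SimScenario | None" = None
    ) -> np.ndarray:
        """Closed-form expected ΔTOP1cc (log2) per gene TSS region."""
        sc = scenario or self.scenario
        delta = sc.delta_for(genotype)
        protected = (
            sc.protection_rho * self.gene_occupied
            if genotype == "control"
            else np.zeros(len(self.gene_occupied))
        )
        factor = 1.0 + delta * self.gene_expression_norm * (1.0 - protected)
        return np.log2(factor)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": asdict(self.scenario),
            "rng_seed": self.rng_seed,
            "chromosomes": self.layout.chromosomes,
            "blacklist": [
                [iv.chrom, iv.start, iv.end] for iv in self.layout.blacklist
            ],
            "hotspots": [
                {
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "gene_id": g,
                    "expression_norm": float(e),
                    "occupied": bool(m),
                }
                for iv, g, e, m in zip(
                    self.hotspots,
                    self.hotspot_gene_id,
                    self.hotspot_expression_norm,
                    self.hotspot_occupied,
                )
            ],
            "domains": [[iv.chrom, iv.start, iv.end] for iv in self.domains],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def recovery_windows(
    truth: SimTruth,
    genes_with_quartiles,
    quartile: str = "Q4",
    halfwidth: int = 250,
    isolation_bp: int = 3000,
) -> tuple[IntervalSet, np.ndarray]:
    """Center windows of covered, expression-selected, isolated hotspots.

    Selects hotspots that are (a) TSS-linked to a gene in the requested
    expression quartile, (b) covered by a macroH2A1.1 domain (m_h = 1) and
    (c) isolated — no other hotspot midpoint within ``isolation_bp`` — so
    that the window signal has a single fragment source and the closed-form
    per-hotspot expectation applies without contamination from neighboring
    hotspots. Returns (windows of midpoint +/- halfwidth, hotspot indices).
    """
    df = genes_with_quartiles.df
    if "quartile" not in df.columns:
        raise ValueError("gene table lacks quartile labels")
    wanted = set(df.loc[df["quartile"] == quartile, "gene_id"])
    mids_by_chrom: dict[str, np.ndarray] = {}
    for iv in truth.hotspots:
        mids_by_chrom.setdefault(iv.chrom, []).append(iv.midpoint)  # type: ignore[arg-type]
    mids_by_chrom = {c: np.sort(np.asarray(v)) for c, v in mids_by_chrom.items()}

    def isolated(iv: GenomicInterval) -> bool:
        d = np.abs(mids_by_chrom[iv.chrom] - iv.midpoint)
        return d.size < 2 or np.partition(d, 1)[1] > isolation_bp

    idx = [
        k
        for k, (g, m) in enumerate(
            zip(truth.hotspot_gene_id, truth.hotspot_occupied)
        )
        if g in wanted and m and isolated(truth.hotspots[k])
    ]
    windows = []
    for k in idx:
        iv = truth.hotspots[k]
        clen = truth.layout.length_of(iv.chrom)
        windows.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.midpoint - halfwidth),
                min(clen, iv.midpoint + halfwidth),
            )
        )
    return IntervalSet(windows, label=f"recovery_{quartile}"), np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _place_uniform_avoiding(
    rng: np.random.Generator,
    layout: GenomeLayout,
    width: int,
    avoid: list[tuple[str, int, int]],
    max_attempts: int = 1000,
) -> GenomicInterval:
    """Place one interval uniformly at random, rejecting `avoid` overlaps."""
    lengths = np.array([l for _, l in layout.chromosomes], dtype=np.int64)
    valid = np.maximum(lengths - width + 1, 0)
    if valid.sum() <= 0:
        raise ValueError(f"feature of width {width} does not fit in the genome")
    cdf = np.cumsum(valid)
    for _ in range(max_attempts):
        u = int(rng.integers(0, cdf[-1]))
        ci = int(np.searchsorted(cdf, u, side="right"))
        start = u - (cdf[ci - 1] if ci else 0)
        chrom = layout.names[ci]
        end = start + width
        if any(c == chrom and s < end and start < e for c, s, e in avoid):
            continue
        return GenomicInterval(chrom, int(start), int(end))
    raise RuntimeError("could not place feature (genome too crowded)")


def build_synthetic_genome(
    scenario: SimScenario,
) -> tuple[GenomeLayout, GeneTable, SimTruth]:
    """Lay out chromosomes, blacklist, genes, hotspots and domains.

    TSS-linked hotspots are centered on TSS sampled without replacement with
    probability proportional to expression (active genes attract TOP1);
    the remainder are uniform-random. macroH2A1.1 domains cover the
    configured fraction of hotspot midpoints; the rest are placed uniformly.
    """
    sc = scenario
    rng = _rng(sc.rng_seed)
    chroms = [
        (f"chr{i + 1}", sc.chromosome_length) for i in range(sc.n_chromosomes)
    ]
    bare = GenomeLayout(chroms)

    # blacklist: fixed-width artifact regions, non-overlapping
    n_bl = int(round(sc.blacklist_fraction * bare.total_length / sc.blacklist_interval_bp))
    bl_ivs: list[GenomicInterval] = []
    occupied: list[tuple[str, int, int]] = []
    for _ in range(n_bl):
        iv = _place_uniform_avoiding(rng, bare, sc.blacklist_interval_bp, occupied)
        bl_ivs.append(iv)
        occupied.append((iv.chrom, iv.start, iv.end))
    layout = bare.with_blacklist(
        IntervalSet(sorted(bl_ivs, key=lambda v: (v.chrom, v.start)), "blacklist")
    )

    # genes: TSS uniform, off-blacklist
    gene_rows = []
    for g in range(sc.n_genes):
        iv = _place_uniform_avoiding(rng, bare, 1, occupied)
        gene_rows.append(
            {
                "gene_id": f"gene{g:04d}",
                "chrom": iv.chrom,
                "tss": iv.start,
                "strand": "+" if rng.random() < 0.5 else "-",
                "expression": float(
                    rng.lognormal(sc.expression_log_mean, sc.expression_log_sd)
                ),
            }
        )
    genes = GeneTable(
        pd.DataFrame(
            gene_rows,
            columns=["gene_id", "chrom", "tss", "strand", "expression"],
        )
    )

    # TOP1 hotspots
    expr = genes.df["expression"].to_numpy()
    e_norm_all = expr / expr.max() if len(expr) else expr
    n_linked = int(round(sc.tss_linked_fraction * sc.n_hotspots))
    n_linked = min(n_linked, sc.n_genes)
    if sc.n_hotspots and sc.n_genes == 0 and sc.tss_linked_fraction > 0:
        raise ValueError("TSS-linked hotspots requested but no genes")
    widths = np.maximum(
        rng.normal(sc.hotspot_width_mean, sc.hotspot_width_sd, sc.n_hotspots), 200
    ).astype(np.int64)
    linked_gene_idx = (
        rng.choice(
            sc.n_genes, size=n_linked, replace=False, p=expr / expr.sum()
        )
        if n_linked
        else np.array([], dtype=int)
    )
    hot_ivs: list[GenomicInterval] = []
    hot_gene: list[str | None] = []
    hot_e: list[float] = []
    for k in range(sc.n_hotspots):
        w = int(widths[k])
        if k < n_linked:
            row = genes.df.iloc[int(linked_gene_idx[k])]
            clen = layout.length_of(row.chrom)
            start = int(np.clip(row.tss - w // 2, 0, max(clen - w, 0)))
            hot_ivs.append(GenomicInterval(row.chrom, start, start + w))
            hot_gene.append(str(row.gene_id))
            hot_e.append(float(e_norm_all[int(linked_gene_idx[k])]))
        else:
            iv = _place_uniform_avoiding(rng, bare, w, occupied)
            hot_ivs.append(iv)
            hot_gene.append(None)
            hot_e.append(0.0)
    hotspots = IntervalSet(hot_ivs, label="top1_hotspots")

    # macroH2A1.1 domains: cover a fraction of hotspot midpoints
    n_cover = int(round(sc.domain_hotspot_overlap_fraction * sc.n_hotspots))
    if n_cover > sc.n_domains:
        raise ValueError(
            f"cannot cover {n_cover} hotspots with {sc.n_domains} domains"
        )
    dom_widths = np.maximum(
        rng.normal(sc.domain_width_mean, sc.domain_width_sd, sc.n_domains), 1000
    ).astype(np.int64)
    cover_idx = (
        rng.choice(sc.n_hotspots, size=n_cover, replace=False)
        if n_cover
        else np.array([], dtype=int)
    )
    dom_ivs: list[GenomicInterval] = []
    for k in range(sc.n_domains):
        w = int(dom_widths[k])
        if k < n_cover:
            mid = hot_ivs[int(cover_idx[k])].midpoint
            chrom = hot_ivs[int(cover_idx[k])].chrom
            clen = layout.length_of(chrom)
            # jitter the domain while keeping the hotspot midpoint inside
            lo = max(0, mid - w + 1)
            hi = min(clen - w, mid)
            start = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
            dom_ivs.append(GenomicInterval(chrom, start, start + w))
        else:
            dom_ivs.append(_place_uniform_avoiding(rng, bare, w, occupied))
    domains = IntervalSet(dom_ivs, label="mh2a11_domains")

    # occupancy: does any domain cover the hotspot midpoint / gene TSS?
    m = np.zeros(sc.n_hotspots, dtype=bool)
    for d in dom_ivs:
        for k, h in enumerate(hot_ivs):
            if not m[k] and d.chrom == h.chrom and d.start <= h.midpoint < d.end:
                m[k] = True
    m_gene = np.zeros(sc.n_genes, dtype=bool)
    for d in dom_ivs:
        for g, row in enumerate(gene_rows):
            if (
                not m_gene[g]
                and d.chrom == row["chrom"]
                and d.start <= row["tss"] < d.end
            ):
                m_gene[g] = True
    truth = SimTruth(
        layout=layout,
        genes=genes,
        hotspots=hotspots,
        domains=domains,
        hotspot_gene_id=hot_gene,
        hotspot_expression_norm=np.asarray(hot_e),
        hotspot_occupied=m,
        gene_expression_norm=np.asarray(e_norm_all, dtype=float),
        gene_occupied=m_gene,
        scenario=sc,
        rng_seed=sc.rng_seed,
    )
    return layout, genes, truth


# ---------------------------------------------------------------------------
# fragment simulators
# ---------------------------------------------------------------------------

def _fragments_from_midpoints(
    rng: np.random.Generator,
    layout: GenomeLayout,
    chrom_idx: np.ndarray,
    mids: np.ndarray,
    length_mean: float,
    length_sd: float,
    min_length: int,
    label: str,
    spike_fraction: float,
    spike_basis: int | None = None,
) -> FragmentSet:
    """Assemble fragments around midpoints and attach a spike-in count.

    ``spike_basis`` is the depth proxy the spike count is binomial in: the
    exogenous spike-in material is constant per sample, so its read count
    tracks sequencing depth, not biological signal. Libraries simulated at a
    common nominal depth should pass that nominal size so that
    condition-dependent signal changes are not absorbed by spike scaling.
    Defaults to the library size itself (appropriate when the library size
    is the nominal depth)."""
    lengths = np.maximum(
        np.rint(rng.normal(length_mean, length_sd, mids.size)), min_length
    ).astype(np.int64)
    if spike_basis is None:
        spike_basis = mids.size
    names = layout.names
    clens = np.array([l for _, l in layout.chromosomes], dtype=np.int64)
    starts = mids - lengths // 2
    ends = starts + lengths
    starts = np.maximum(starts, 0)
    ends = np.minimum(ends, clens[chrom_idx])
    ivs = [
        GenomicInterval(names[c], int(s), int(e))
        for c, s, e in zip(chrom_idx, starts, ends)
        if e > s
    ]
    spike = int(rng.binomial(spike_basis, spike_fraction)) if spike_basis else 0
    return FragmentSet(IntervalSet(ivs, label=label), spike, label)


def _uniform_genome_positions(
    rng: np.random.Generator, layout: GenomeLayout, n: int
) -> tuple[np.ndarray, np.ndarray]:
    clens = np.array([l for _, l in layout.chromosomes], dtype=np.int64)
    cdf = np.cumsum(clens)
    u = rng.integers(0, cdf[-1], size=n)
    ci = np.searchsorted(cdf, u, side="right")
    offs = u - np.where(ci > 0, cdf[np.maximum(ci - 1, 0)], 0)
    return ci, offs


def _positions_within(
    rng: np.random.Generator,
    layout: GenomeLayout,
    intervals: IntervalSet,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """n positions uniform over the bp covered by `intervals` (with
    multiplicity if intervals overlap)."""
    name_to_idx = {c: i for i, c in enumerate(layout.names)}
    starts = np.array([iv.start for iv in intervals], dtype=np.int64)
    widths = np.array([len(iv) for iv in intervals], dtype=np.int64)
    chrom = np.array([name_to_idx[iv.chrom] for iv in intervals], dtype=np.int64)
    cdf = np.cumsum(widths)
    u = rng.integers(0, cdf[-1], size=n)
    k = np.searchsorted(cdf, u, side="right")
    offs = u - np.where(k > 0, cdf[np.maximum(k - 1, 0)], 0)
    return chrom[k], starts[k] + offs


def simulate_cutrun_fragments(
    truth: SimTruth,
    target: str,
    scenario: SimScenario | None = None,
    seed: int = 0,
) -> FragmentSet:
    """A CUT&RUN-like fragment library for one antibody target.

    Fragment midpoints follow the mixture density w(x) = F inside the
    target's true intervals and 1 elsewhere, with F the enrichment fold;
    IgG is pure background (F = 1 everywhere). Fragment lengths are normal
    (clipped at 20 bp) and fragments are clipped to chromosome bounds. The
    spike-in count is binomial in the library size.
    """
    sc = scenario or truth.scenario
    if target not in CUTRUN_TARGETS:
        raise ValueError(f"unknown target {target!r}; expected one of {CUTRUN_TARGETS}")
    rng = _rng(seed)
    layout = truth.layout
    n = sc.cutrun_fragment_count
    label = f"cutrun_{target}"
    if n == 0:
        return FragmentSet(IntervalSet([], label=label), 0, label)
    if target == "TOP1":
        target_ivs = truth.hotspots
    elif target == "macroH2A1.1":
        target_ivs = truth.domains
    else:
        target_ivs = IntervalSet([], label="none")
    fold = sc.cutrun_enrichment_fold if len(target_ivs) else 1.0
    target_bp = target_ivs.total_bp()
    genome_bp = layout.total_length
    p_target = (
        fold * target_bp / (fold * target_bp + (genome_bp - target_bp))
        if target_bp
        else 0.0
    )
    n_target = int(rng.binomial(n, p_target)) if p_target > 0 else 0
    parts_ci, parts_mid = [], []
    if n_target:
        ci, mids = _positions_within(rng, layout, target_ivs, n_target)
        parts_ci.append(ci)
        parts_mid.append(mids)
    n_bg = n - n_target
    if n_bg:
        # background excludes the target intervals (they already carry the
        # full weight F); rejection sampling, target bp is a small fraction
        need = n_bg
        from .colocalization import _as_arrays, _merge

        merged_target = {c: _merge(v) for c, v in _as_arrays(target_ivs).items()}
        bl_arrays = {
            c: merged_target.get(c, np.empty((0, 2), dtype=np.int64))
            for c in layout.names
        }
        got_ci, got_mid = [], []
        while need > 0:
            ci, offs = _uniform_genome_positions(rng, layout, int(need * 1.3) + 8)
            keep = np.ones(ci.size, dtype=bool)
            for k, c in enumerate(layout.names):
                arr = bl_arrays[c]
                if arr.size == 0:
                    continue
                on_c = ci == k
                if not on_c.any():
                    continue
                j = np.searchsorted(arr[:, 0], offs[on_c], side="right")
                inside = (j > 0) & (offs[on_c] < arr[np.maximum(j - 1, 0), 1])
                keep[on_c] &= ~inside
            ci, offs = ci[keep][:need], offs[keep][:need]
            got_ci.append(ci)
            got_mid.append(offs)
            need -= ci.size
        parts_ci.append(np.concatenate(got_ci))
        parts_mid.append(np.concatenate(got_mid))
    chrom_idx = np.concatenate(parts_ci)
    mids = np.concatenate(parts_mid)
    return _fragments_from_midpoints(
        rng, layout, chrom_idx, mids,
        sc.cutrun_fragment_length_mean, sc.cutrun_fragment_length_sd, 20,
        label, sc.spike_in_fraction,
    )


def simulate_cadseq_fragments(
    truth: SimTruth,
    condition: str,
    genotype: str,
    scenario: SimScenario | None = None,
    seed: int = 0,
) -> FragmentSet:
    """A CAD-Seq-like fragment library for one condition and genotype.

    Three additive components, each Poisson with seeded draws:

    * hotspot h emits Poisson(lambda_s * w_h * factor_h) fragments with
      midpoints uniform in the hotspot; factor_h is 1 at steady state and
      1 + delta_g * e_h * (1 - rho * m_h * [genotype = control]) under
      prolonged damage;
    * every gene's TSS +/- ``cad_tss_halfwidth`` emits fragments at the TSS
      baseline rate with the same amplification factor evaluated with that
      gene's expression e_g and TSS occupancy m_g — every transcribed gene
      engages TOP1, not only those under a called hotspot;
    * uniform genomic background at the scenario rate.

    The spike-in count is binomial in the condition-invariant nominal depth
    (see :func:`_fragments_from_midpoints`).
    """
    sc = scenario or truth.scenario
    if condition not in CAD_CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CAD_CONDITIONS}"
        )
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    rng = _rng(seed)
    layout = truth.layout
    label = f"cad_{condition}_{genotype}"

    widths = np.array([len(iv) for iv in truth.hotspots], dtype=np.int64)
    base = sc.cad_rate_per_bp * widths.astype(float)
    if condition == "prolonged_30min":
        factor = 2.0 ** truth.expected_delta_top1cc(genotype, sc)
    else:
        factor = np.ones_like(base)
    counts = rng.poisson(base * factor) if len(widths) else np.array([], dtype=int)

    parts_ci, parts_mid = [], []
    name_to_idx = {c: i for i, c in enumerate(layout.names)}
    for k, iv in enumerate(truth.hotspots):
        c = counts[k]
        if c == 0:
            continue
        mids = rng.integers(iv.start, iv.end, size=c)
        parts_ci.append(np.full(c, name_to_idx[iv.chrom], dtype=np.int64))
        parts_mid.append(mids)
    # TSS component: every gene emits at the baseline rate with the same
    # turnover amplification, evaluated per gene
    tss_w = 2 * sc.cad_tss_halfwidth
    n_genes = len(truth.genes)
    if n_genes and sc.cad_tss_rate_per_bp > 0:
        tss_base = np.full(n_genes, sc.cad_tss_rate_per_bp * tss_w)
        if condition == "prolonged_30min":
            tss_factor = 2.0 ** truth.expected_delta_top1cc_tss(genotype, sc)
        else:
            tss_factor = np.ones(n_genes)
        tss_counts = rng.poisson(tss_base * tss_factor)
        for g, row in enumerate(truth.genes.df.itertuples()):
            c = tss_counts[g]
            if c == 0:
                continue
            clen = layout.length_of(row.chrom)
            lo = max(0, row.tss - sc.cad_tss_halfwidth)
            hi = min(clen, row.tss + sc.cad_tss_halfwidth)
            parts_ci.append(np.full(c, name_to_idx[row.chrom], dtype=np.int64))
            parts_mid.append(rng.integers(lo, hi, size=c))
    n_bg = int(rng.poisson(sc.cad_background_per_bp * layout.total_length))
    if n_bg:
        ci, offs = _uniform_genome_positions(rng, layout, n_bg)
        parts_ci.append(ci)
        parts_mid.append(offs)
    if parts_ci:
        chrom_idx = np.concatenate(parts_ci)
        mids = np.concatenate(parts_mid)
    else:
        chrom_idx = np.array([], dtype=np.int64)
        mids = np.array([], dtype=np.int64)
    nominal_depth = int(round(
        sc.cad_rate_per_bp * float(widths.sum())
        + sc.cad_tss_rate_per_bp * tss_w * n_genes
        + sc.cad_background_per_bp * layout.total_length
    ))
    return _fragments_from_midpoints(
        rng, layout, chrom_idx, mids,
        sc.cad_fragment_length_mean, sc.cad_fragment_length_sd, 100,
        label, sc.spike_in_fraction, spike_basis=nominal_depth,
    )
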