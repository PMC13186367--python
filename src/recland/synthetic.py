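"""Synthetic genomes with planted structure for end-to-end verification.

The generator emulates every input the pipeline consumes — a
multi-chromosome layout, non-overlapping gene models with log-normal
lengths and expression, repeat families at target genomic fractions,
blacklist and zero-coverage masks, hotspot sets and a piecewise-constant
recombination map — and records the planted parameters (per-family
hotspot enrichment factors, per-quantile hotspot density factors,
per-class gene-body rate suppression) in a ground-truth object so every
analysis stage can be checked for parameter recovery without any
external download.

Hotspots are placed by thinning: candidates are drawn uniformly over
all legal placements in the callable mask and accepted with probability
proportional to the product of the planted factors active at the
candidate's center, so a planted factor is exactly the ratio of
placement densities it claims to be.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GenomeLayout,
    PeakSet,
    build_callable_mask,
    intervals_frame,
    merge_intervals,
    points_in_intervals,
    uniform_placements,
    validate_intervals,
)
from .density import assign_expression_categories
from .io import (
    RecombinationMap,
    RepeatAnnotation,
    add_tss_tes,
    validate_recmap,
    write_chrom_sizes,
    write_expression_tsv,
    write_genes_gtf,
    write_intervals,
    write_recmap_bedgraph,
    write_repeatmasker,
    write_table,
)
from .ranking import rank_split


@dataclass(frozen=True)
class LogNormalLaw:
    """Log-normal sampling law; mean/sd on the natural-log scale."""

    mean_log: float
    sd_log: float

    def __post_init__(self):
        if self.sd_log < 0:
            raise ValueError("sd_log must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.mean_log, self.sd_log, n)

    def sample_lengths(self, rng: np.random.Generator, n: int, minimum: int = 1) -> np.ndarray:
        return np.maximum(minimum, np.round(self.sample(rng, n))).astype(np.int64)


@dataclass(frozen=True)
class RepeatFamilyParams:
    fraction: float                 # target genomic fraction of the family
    length_law: LogNormalLaw


@dataclass(frozen=True)
class RecmapParams:
    """Piecewise-constant recombination-map structure.

    Background rate in cM/Mb, multiplicatively elevated within
    `tss_peak_halfwidth` bp of every TSS and suppressed inside the
    bodies of genes of each expression class (1..n_classes, class
    n_classes = most expressed).
    """

    background_rate: float = 1.0
    tss_peak_factor: float = 5.0
    tss_peak_halfwidth: int = 1000
    n_classes: int = 3
    genebody_suppression: dict = field(default_factory=lambda: {3: 0.5})


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 2_500_000
    n_genes: int = 400
    gene_length_law: LogNormalLaw = LogNormalLaw(math.log(8000), 0.6)
    expression_law: LogNormalLaw = LogNormalLaw(1.0, 1.5)
    zero_expression_fraction: float = 0.10
    repeat_families: dict = field(default_factory=lambda: {
        "L1": RepeatFamilyParams(0.10, LogNormalLaw(math.log(900), 0.8)),
        "MaLR": RepeatFamilyParams(0.04, LogNormalLaw(math.log(350), 0.5)),
        "MIR": RepeatFamilyParams(0.03, LogNormalLaw(math.log(200), 0.4)),
        "Simple_repeat": RepeatFamilyParams(0.02, LogNormalLaw(math.log(80), 0.6)),
    })
    blacklist_fraction: float = 0.02
    blacklist_run_law: LogNormalLaw = LogNormalLaw(math.log(5000), 0.5)
    zero_cov_fraction: float = 0.03
    zero_cov_run_law: LogNormalLaw = LogNormalLaw(math.log(1200), 0.8)
    min_zero_run: int = 1000
    n_hotspots: int = 2000
    hotspot_width_law: LogNormalLaw = LogNormalLaw(math.log(500), 0.3)
    planted_family_enrichment: dict = field(default_factory=dict)   # family -> factor
    planted_halfwidth: int = 100
    planted_expression_density: dict = field(default_factory=dict)  # quantile -> factor
    n_quantiles: int = 5
    recmap: RecmapParams = RecmapParams()

    def validate(self) -> "SyntheticConfig":
        for name, frac in (("blacklist_fraction", self.blacklist_fraction),
                           ("zero_cov_fraction", self.zero_cov_fraction),
                           ("zero_expression_fraction", self.zero_expression_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        total = self.blacklist_fraction + self.zero_cov_fraction + \
            sum(p.fraction for p in self.repeat_families.values())
        if total >= 0.9:
            raise ValueError(f"annotated fractions sum to {total:.2f}; must stay below 0.9")
        for name, factors in (("planted_family_enrichment", self.planted_family_enrichment),
                              ("planted_expression_density", self.planted_expression_density)):
            for key, f in factors.items():
                if f <= 0:
                    raise ValueError(f"{name}[{key!r}] must be > 0, got {f}")
        for cls, f in self.recmap.genebody_suppression.items():
            if f <= 0:
                raise ValueError(f"genebody_suppression[{cls}] must be > 0")
        if self.n_chromosomes < 1 or self.chromosome_length < 1 or self.n_genes < 1:
            raise ValueError("genome dimensions must be positive")
        return self

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        def law(d):
            return LogNormalLaw(**d)
        kwargs = dict(raw)
        for key in ("gene_length_law", "expression_law", "blacklist_run_law",
                    "zero_cov_run_law", "hotspot_width_law"):
            if key in kwargs:
                kwargs[key] = law(kwargs[key])
        if "repeat_families" in kwargs:
            kwargs["repeat_families"] = {
                fam: RepeatFamilyParams(p["fraction"], law(p["length_law"]))
                for fam, p in kwargs["repeat_families"].items()
            }
        if "recmap" in kwargs:
            rm = dict(kwargs["recmap"])
            if "genebody_suppression" in rm:
                rm["genebody_suppression"] = {int(k): v for k, v in rm["genebody_suppression"].items()}
            kwargs["recmap"] = RecmapParams(**rm)
        if "planted_expression_density" in kwargs:
            kwargs["planted_expression_density"] = {
                int(k): v for k, v in kwargs["planted_expression_density"].items()
            }
        return cls(**kwargs).validate()


@dataclass(frozen=True)
class Annotation:
    """Everything the pipeline reads except the peaks and the map."""

    layout: GenomeLayout
    genes: pd.DataFrame
    expression: pd.Series
    repeats: RepeatAnnotation
    blacklist: pd.DataFrame
    zero_coverage: pd.DataFrame


@dataclass
class GroundTruth:
    """Planted parameters written alongside every generated dataset."""

    family_enrichment: dict = field(default_factory=dict)
    expression_density: dict = field(default_factory=dict)
    genebody_suppression: dict = field(default_factory=dict)
    category_assignment: dict = field(default_factory=dict)  # gene_id -> quantile
    class_assignment: dict = field(default_factory=dict)     # gene_id -> tertile class

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam, f in sorted(self.family_enrichment.items()):
            rows.append(("family_enrichment", fam, f))
        for cat, f in sorted(self.expression_density.items()):
            rows.append(("expression_density", str(cat), f))
        for cls, f in sorted(self.genebody_suppression.items()):
            rows.append(("genebody_suppression", str(cls), f))
        for gid, cat in sorted(self.category_assignment.items()):
            rows.append(("category_assignment", gid, float(cat)))
        for gid, cls in sorted(self.class_assignment.items()):
            rows.append(("class_assignment", gid, float(cls)))
        return pd.DataFrame(rows, columns=["kind", "key", "value"])


def _place_uniform_runs(rng: np.random.Generator, layout: GenomeLayout,
                        length_law: LogNormalLaw, target_bp: int) -> pd.DataFrame:
    """Place runs uniformly (overlaps allowed) until nominal lengths reach target_bp."""
    if target_bp <= 0:
        return intervals_frame()
    names = layout.names
    clens = np.array([layout.length_of(c) for c in names], dtype=np.int64)
    probs = clens / clens.sum()
    rows = []
    placed = 0
    while placed < target_bp:
        n_batch = max(16, int((target_bp - placed) / max(1, math.exp(length_law.mean_log))))
        lengths = length_law.sample_lengths(rng, n_batch)
        chrom_idx = rng.choice(len(names), size=n_batch, p=probs)
        for L, ci in zip(lengths, chrom_idx):
            L = int(min(L, clens[ci]))
            start = int(rng.integers(0, clens[ci] - L + 1))
            rows.append((names[ci], start, start + L))
            placed += L
            if placed >= target_bp:
                break
    return intervals_frame(rows)


def simulate_annotation(config: SyntheticConfig) -> Annotation:
    """Genome layout, gene models, expression, repeats and masks.

    Genes are placed uniformly without overlap by rejection sampling
    (error after a retry cap suggests lowering n_genes or lengths);
    repeats, blacklist runs and zero-coverage runs are placed uniformly
    with overlaps allowed until each reaches its target fraction.
    Deterministic given config.seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = GenomeLayout({f"chr{i + 1}": config.chromosome_length
                           for i in range(config.n_chromosomes)})
    names = layout.names
    clens = np.array([layout.length_of(c) for c in names], dtype=np.int64)
    probs = clens / clens.sum()

    # genes: uniform, non-overlapping, rejection sampled; longest first so
    # tail-of-the-law genes still find a gap late in the packing
    occupied: dict[str, list] = {c: [] for c in names}
    gene_rows = []
    max_tries = 1000
    gene_lengths = np.sort(config.gene_length_law.sample_lengths(
        rng, config.n_genes, minimum=200))[::-1]
    for length in gene_lengths:
        length = int(length)
        for attempt in range(max_tries):
            ci = int(rng.choice(len(names), p=probs))
            clen = int(clens[ci])
            if length >= clen:
                length = clen // 2
            start = int(rng.integers(0, clen - length + 1))
            end = start + length
            occ = occupied[names[ci]]
            if all(end <= s or start >= e for s, e in occ):
                occ.append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append((names[ci], start, end, strand))
                break
        else:
            raise ValueError(
                "could not place all genes without overlap; lower n_genes or gene lengths"
            )
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand"])
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    genes.insert(0, "gene_id", [f"g{i + 1:05d}" for i in range(len(genes))])
    genes = add_tss_tes(genes)
    validate_intervals(genes, layout, "gene")

    expr_values = config.expression_law.sample(rng, len(genes))
    n_zero = int(round(config.zero_expression_fraction * len(genes)))
    if n_zero:
        zero_idx = rng.choice(len(genes), size=n_zero, replace=False)
        expr_values[zero_idx] = 0.0
    expression = pd.Series(expr_values, index=genes["gene_id"].to_numpy(), name="expression")

    genome_bp = layout.total_length
    repeat_frames = []
    for family, params in config.repeat_families.items():
        df = _place_uniform_runs(rng, layout, params.length_law,
                                 int(params.fraction * genome_bp))
        df["family"] = family
        repeat_frames.append(df)
    repeats_df = pd.concat(repeat_frames, ignore_index=True) if repeat_frames \
        else intervals_frame().assign(family=pd.Series(dtype=str))
    repeats_df = repeats_df.sort_values(["chrom", "start", "family"],
                                        kind="mergesort").reset_index(drop=True)
    repeats = RepeatAnnotation(records=repeats_df, retained=len(repeats_df), dropped=0)

    blacklist = merge_intervals(
        _place_uniform_runs(rng, layout, config.blacklist_run_law,
                            int(config.blacklist_fraction * genome_bp)), layout)
    zero_cov = merge_intervals(
        _place_uniform_runs(rng, layout, config.zero_cov_run_law,
                            int(config.zero_cov_fraction * genome_bp)), layout)
    return Annotation(layout=layout, genes=genes, expression=expression,
                      repeats=repeats, blacklist=blacklist, zero_coverage=zero_cov)


def expand_for_center_window(df: pd.DataFrame, halfwidth: int, layout: GenomeLayout) -> pd.DataFrame:
    """Region of centers whose +/- halfwidth window intersects the elements.

    A center c has window [c-halfwidth, c+halfwidth) (1 bp at c when
    halfwidth is 0); that window shares a base with element [s, e)
    exactly when c lies in [s-halfwidth+1, e+halfwidth-1+1), which this
    returns (merged, clipped).
    """
    if df.empty:
        return intervals_frame()
    pad = max(halfwidth - 1, 0)
    clens = df["chrom"].map(layout.chromosomes).to_numpy(np.int64)
    out = pd.DataFrame({
        "chrom": df["chrom"].to_numpy(),
        "start": np.maximum(0, df["start"].to_numpy(np.int64) - pad),
        "end": np.minimum(clens, df["end"].to_numpy(np.int64) + pad + 1),
    })
    return merge_intervals(out, layout)


def simulate_hotspots(config: SyntheticConfig, annotation: Annotation,
                      rng: np.random.Generator | None = None) -> tuple[PeakSet, GroundTruth]:
    """Hotspots inside the callable mask with planted placement factors.

    The placement density over the callable genome is uniform,
    multiplied by ``planted_family_enrichment[F]`` when the hotspot
    center falls within +/- `planted_halfwidth` of a family-F element
    and by ``planted_expression_density[q]`` when it falls inside the
    (blacklist-subtracted) territory of expression quantile q.
    Implemented by thinning, so each factor is exactly a placement
    density ratio.
    """
    config.validate()
    if config.n_hotspots < 1:
        raise ValueError("n_hotspots must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    mask = build_callable_mask(annotation.layout, annotation.blacklist,
                               annotation.zero_coverage, config.min_zero_run)

    family_regions = {}
    for family, factor in config.planted_family_enrichment.items():
        if family not in annotation.repeats.families:
            raise ValueError(f"planted enrichment for unknown repeat family {family!r}")
        family_regions[family] = expand_for_center_window(
            annotation.repeats.family_frame(family), config.planted_halfwidth, annotation.layout)

    truth = GroundTruth(family_enrichment=dict(config.planted_family_enrichment),
                        expression_density=dict(config.planted_expression_density))
    category_regions = {}
    if config.planted_expression_density:
        cats = assign_expression_categories(
            annotation.genes, annotation.expression, config.n_quantiles,
            layout=annotation.layout, blacklist=annotation.blacklist)
        truth.category_assignment = {g: int(c) for g, c in cats.assignment.items()}
        for q, factor in config.planted_expression_density.items():
            if not 1 <= q <= config.n_quantiles:
                raise ValueError(f"planted density for unknown quantile {q}")
            category_regions[q] = cats.territories[q]

    max_factor = max([1.0] + list(config.planted_family_enrichment.values())) * \
        max([1.0] + list(config.planted_expression_density.values()))

    accepted = []
    n_needed = config.n_hotspots
    for _ in range(200):
        if n_needed <= 0:
            break
        batch = max(1000, 2 * n_needed)
        widths = config.hotspot_width_law.sample_lengths(rng, batch, minimum=50)
        placed = uniform_placements(widths, mask, rng)
        centers = (placed["start"].to_numpy(np.int64) + placed["end"].to_numpy(np.int64)) // 2
        chroms = placed["chrom"].to_numpy()
        factor = np.ones(batch)
        for family, region in family_regions.items():
            inside = points_in_intervals(chroms, centers, region)
            factor[inside] *= config.planted_family_enrichment[family]
        for q, region in category_regions.items():
            inside = points_in_intervals(chroms, centers, region)
            factor[inside] *= config.planted_expression_density[q]
        keep = rng.random(batch) < factor / max_factor
        kept = placed[keep]
        accepted.append(kept)
        n_needed -= len(kept)
    else:
        raise ValueError("hotspot thinning did not converge; planted factors too extreme")
    out = pd.concat(accepted, ignore_index=True).head(config.n_hotspots)
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return PeakSet(label="synthetic_hotspots", intervals=out), truth


def simulate_recmap(config: SyntheticConfig, annotation: Annotation) -> tuple[RecombinationMap, GroundTruth]:
    """Piecewise-constant recombination map with planted structure.

    Background everywhere; multiplied by the TSS peak factor within the
    TSS halfwidth of every expressed-gene TSS; multiplied by the
    per-class gene-body suppression inside gene bodies. Expression
    classes are the same rank tertiles (expression > 0 only) the
    profile stage reconstructs. Deterministic given the annotation.
    """
    params = config.recmap
    genes = annotation.genes
    expressed = genes[genes["gene_id"].map(annotation.expression).fillna(0.0) > 0]
    classes = rank_split(expressed["gene_id"].to_numpy(),
                         expressed["gene_id"].map(annotation.expression).to_numpy(float),
                         params.n_classes)
    truth = GroundTruth(genebody_suppression=dict(params.genebody_suppression),
                        class_assignment={g: int(c) for g, c in classes.items()})

    rows = []
    for chrom in annotation.layout.names:
        clen = annotation.layout.length_of(chrom)
        events: list[tuple[int, float]] = []

        def add_region(s: int, e: int, f: float):
            if f == 1.0:
                return
            s, e = max(0, s), min(clen, e)
            if s < e:
                events.append((s, math.log(f)))
                events.append((e, -math.log(f)))

        sub = expressed[expressed["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            if params.tss_peak_factor != 1.0:
                add_region(row.tss - params.tss_peak_halfwidth,
                           row.tss + params.tss_peak_halfwidth, params.tss_peak_factor)
            cls = int(classes[row.gene_id])
            supp = params.genebody_suppression.get(cls, 1.0)
            add_region(row.start, row.end, supp)
        breaks = np.unique(np.array([0, clen] + [p for p, _ in events], dtype=np.int64))
        delta = np.zeros(breaks.size)
        for pos, logf in events:
            delta[np.searchsorted(breaks, pos)] += logf
        cumlog = np.cumsum(delta)
        seg_rate = params.background_rate * np.exp(cumlog[:-1])
        seg_s, seg_e = breaks[:-1], breaks[1:]
        # merge runs of equal rate
        keep = np.ones(seg_rate.size, dtype=bool)
        keep[1:] = ~np.isclose(seg_rate[1:], seg_rate[:-1], rtol=1e-12, atol=0)
        idx = np.flatnonzero(keep)
        ends = np.append(idx[1:], seg_rate.size) - 1
        for i, j in zip(idx, ends):
            rows.append((chrom, int(seg_s[i]), int(seg_e[j]), float(seg_rate[i])))
    recmap_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"])
    recmap_df["start"] = recmap_df["start"].astype(np.int64)
    recmap_df["end"] = recmap_df["end"].astype(np.int64)
    return validate_recmap(recmap_df, annotation.layout), truth


def simulate_dataset(config: SyntheticConfig):
    """Convenience: annotation + hotspots + recombination map + merged truth."""
    annotation = simulate_annotation(config)
    hotspots, truth_h = simulate_hotspots(config, annotation)
    recmap, truth_r = simulate_recmap(config, annotation)
    truth = GroundTruth(
        family_enrichment=truth_h.family_enrichment,
        expression_density=truth_h.expression_density,
        genebody_suppression=truth_r.genebody_suppression,
        category_assignment=truth_h.category_assignment,
        class_assignment=truth_r.class_assignment,
    )
    return annotation, hotspots, recmap, truth


def write_dataset(outdir: str | Path, annotation: Annotation, hotspots: PeakSet,
                  recmap: RecombinationMap, truth: GroundTruth) -> dict[str, Path]:
    """Write a generated dataset in the pipeline's on-disk input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "genes": outdir / "genes.gtf",
        "expression": outdir / "expression.tsv",
        "repeats": outdir / "repeats_rmsk.tsv",
        "blacklist": outdir / "blacklist.bed",
        "zero_coverage": outdir / "zero_coverage.bed",
        "hotspots": outdir / "hotspots.bed",
        "recmap": outdir / "recmap.bedgraph",
        "truth": outdir / "truth.tsv",
    }
    write_chrom_sizes(annotation.layout, paths["chrom_sizes"])
    write_genes_gtf(annotation.genes, paths["genes"])
    write_expression_tsv(annotation.expression, paths["expression"])
    write_repeatmasker(annotation.repeats.records, paths["repeats"])
    write_intervals(annotation.blacklist, paths["blacklist"])
    write_intervals(annotation.zero_coverage, paths["zero_coverage"])
    write_intervals(hotspots.intervals[["chrom", "start", "end"]], paths["hotspots"])
    write_recmap_bedgraph(recmap, paths["recmap"])
    write_table(truth.to_frame(), paths["truth"])
    return paths
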