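"""Relative hotspot/event density across meiotic-expression categories.

Genes are split into ``n_quantiles`` near-equal groups by expression
rank; each group's territory is the merged union of its members' spans
minus the blacklist, and everything outside annotated genes (and outside
the blacklist) forms the additional "intergenic" category. The density
of a peak/event set in a category is

    density_c        = k_c / L_c                (events per bp)
    relative_density = (k_c / L_c) / N

where ``k_c`` is the number of events assigned to the category, ``L_c``
the territory length and ``N`` the total number of events genome-wide
outside the blacklist. The binomial sampling error on the relative
density is ``sqrt(p(1-p)/N) / L_c`` with ``p = k_c/N``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    GenomeLayout,
    PeakSet,
    complement,
    count_overlapping,
    covered_bp,
    intervals_frame,
    merge_intervals,
    points_in_intervals,
    subtract_intervals,
)
from .ranking import rank_split

logger = logging.getLogger(__name__)

INTERGENIC = "intergenic"


@dataclass(frozen=True)
class ExpressionCategories:
    """Quantile categories of gene expression plus the intergenic remainder.

    `assignment` maps gene_id -> quantile index 1..n (1 = lowest
    expression). `territories` maps category key (int quantile index or
    "intergenic") to a merged interval frame excluding blacklisted
    bases; `territory_length` holds the per-category covered bp.
    """

    n_quantiles: int
    assignment: pd.Series
    territories: dict
    territory_length: dict
    blacklist: pd.DataFrame
    layout: GenomeLayout

    @property
    def category_keys(self) -> list:
        return list(range(1, self.n_quantiles + 1)) + [INTERGENIC]


def assign_expression_categories(
    genes: pd.DataFrame,
    expression: pd.Series,
    n_quantiles: int = 5,
    *,
    layout: GenomeLayout,
    blacklist: pd.DataFrame | None = None,
    missing: str = "drop",
) -> ExpressionCategories:
    """Rank genes by expression and build per-quantile genomic territories.

    Genes without an expression value are dropped (default) or assigned
    zero expression (``missing="zero"``); dropped genes contribute
    neither to any quantile territory nor to holes in the intergenic
    territory. Zero-expression genes are kept and fall into the bottom
    quantile(s).
    """
    if missing not in ("drop", "zero"):
        raise ValueError("missing must be 'drop' or 'zero'")
    if blacklist is None or blacklist.empty:
        blacklist = intervals_frame()
    genes = genes.reset_index(drop=True)
    have = genes["gene_id"].isin(expression.index)
    if not have.all():
        n_missing = int((~have).sum())
        if missing == "drop":
            logger.info("dropping %d genes without expression values", n_missing)
            genes = genes[have].reset_index(drop=True)
        else:
            logger.info("assigning zero expression to %d genes", n_missing)
    if len(genes) < n_quantiles:
        raise ValueError(f"only {len(genes)} genes with expression for {n_quantiles} quantiles")
    values = np.array([float(expression.get(g, 0.0)) for g in genes["gene_id"]])
    assignment = rank_split(genes["gene_id"].to_numpy(), values, n_quantiles)

    territories: dict = {}
    lengths: dict = {}
    for cat in range(1, n_quantiles + 1):
        members = genes[assignment.loc[genes["gene_id"]].to_numpy() == cat]
        spans = members[["chrom", "start", "end"]]
        terr = subtract_intervals(spans, blacklist, layout) if not blacklist.empty \
            else merge_intervals(spans, layout)
        territories[cat] = terr
        lengths[cat] = covered_bp(terr)
    all_spans = pd.concat([genes[["chrom", "start", "end"]], blacklist], ignore_index=True) \
        if not blacklist.empty else genes[["chrom", "start", "end"]]
    intergenic = complement(all_spans, layout)
    territories[INTERGENIC] = intergenic
    lengths[INTERGENIC] = covered_bp(intergenic)
    return ExpressionCategories(
        n_quantiles=n_quantiles,
        assignment=assignment,
        territories=territories,
        territory_length=lengths,
        blacklist=merge_intervals(blacklist, layout) if not blacklist.empty else blacklist,
        layout=layout,
    )


def peak_density_by_category(
    peaks: PeakSet,
    categories: ExpressionCategories,
    assignment_mode: str = "midpoint",
) -> pd.DataFrame:
    """Per-category event counts and normalised densities.

    ``midpoint`` mode assigns each event to the single category whose
    territory contains its center (a center falling in overlapping gene
    territories of two quantiles goes to the higher-expression one), so
    counts sum exactly to N. ``any_overlap`` mode counts an event in
    every category whose territory it intersects.

    Events whose center lies in the blacklist are removed before
    counting and excluded from N.
    """
    if assignment_mode not in ("midpoint", "any_overlap"):
        raise ValueError("assignment_mode must be 'midpoint' or 'any_overlap'")
    df = peaks.intervals.reset_index(drop=True)
    centers = (df["start"].to_numpy(np.int64) + df["end"].to_numpy(np.int64)) // 2
    chroms = df["chrom"].to_numpy()
    if not categories.blacklist.empty:
        in_bl = points_in_intervals(chroms, centers, categories.blacklist)
        df = df[~in_bl].reset_index(drop=True)
        centers = centers[~in_bl]
        chroms = chroms[~in_bl]
    n_total = len(df)
    if n_total == 0:
        raise ValueError("no peaks outside the blacklist: nothing to assign")

    counts: dict = {}
    if assignment_mode == "midpoint":
        assigned = np.zeros(n_total, dtype=bool)
        # priority: highest expression quantile first, intergenic last
        for cat in list(range(categories.n_quantiles, 0, -1)) + [INTERGENIC]:
            terr = categories.territories[cat]
            inside = points_in_intervals(chroms, centers, terr) & ~assigned
            counts[cat] = int(inside.sum())
            assigned |= inside
    else:
        for cat in categories.category_keys:
            _, hit = count_overlapping(df, categories.territories[cat])
            counts[cat] = int(hit.sum())

    rows = []
    for cat in categories.category_keys:
        k = counts[cat]
        length = categories.territory_length[cat]
        p_hat = k / n_total
        if length > 0:
            density = k / length
            rel = density / n_total
            se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_total) / length)
        else:
            density = rel = se = float("nan")  # undefined, not zero
        rows.append({
            "category": f"q{cat}" if cat != INTERGENIC else INTERGENIC,
            "peak_count": k,
            "territory_bp": length,
            "total_peaks": n_total,
            "density": density,
            "relative_density": rel,
            "se_relative": se,
        })
    return pd.DataFrame(rows)
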