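"""Recombination-rate profiles by distance to the nearest TSS or TES.

The genome is scanned in fixed windows; each window midpoint receives a
metagene coordinate — the signed distance to the nearer end (TSS or
TES) of the nearest gene, negative outside the gene and non-negative
inside — and window rates are averaged per (expression class, side,
distance bin), weighting by the bases of recombination map actually
covering each window. Genes are restricted to those with detectable
expression (value > 0) and split into equal-sized classes by expression
rank; each class is profiled against its own genes only.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import GenomeLayout
from .io import RecombinationMap
from .ranking import rank_split

TSS = "TSS"
TES = "TES"


class MetageneCoordinate(NamedTuple):
    side: str       # "TSS" or "TES"
    offset: int     # >= 0 inside the gene, < 0 outside
    gene_id: str


def metagene_coordinate(chrom: str, position: int, genes: pd.DataFrame) -> MetageneCoordinate | None:
    """Metagene coordinate of a single base against a gene collection.

    The position is assigned to the gene minimising the distance to its
    span (0 when inside). Inside a gene the side is the nearer of
    TSS/TES in transcription orientation (ties go to the TSS) and the
    offset is the distance to that end; outside, the side is the gene
    end being flanked (upstream of the TSS -> TSS, downstream of the
    TES -> TES) and the offset is minus the distance to the span.
    Returns None when the chromosome carries no gene.
    """
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return None
    side, offset, idx = _coords_for_positions(np.array([position]), sub)
    return MetageneCoordinate(side[0], int(offset[0]), sub.iloc[idx[0]]["gene_id"])


def _coords_for_positions(positions: np.ndarray, genes: pd.DataFrame):
    """Vectorised metagene coordinates for positions on one chromosome.

    Returns (side array, offset array, nearest-gene positional index).
    O(n_positions * n_genes) by broadcasting; fine at pipeline scales.
    """
    starts = genes["start"].to_numpy(np.int64)
    ends = genes["end"].to_numpy(np.int64)
    strands = genes["strand"].to_numpy()
    tss = genes["tss"].to_numpy(np.int64)
    tes = genes["tes"].to_numpy(np.int64)
    p = positions[:, None]
    dist = np.maximum(np.maximum(starts[None, :] - p, p - (ends[None, :] - 1)), 0)
    nearest = np.argmin(dist, axis=1)
    d = dist[np.arange(positions.size), nearest]
    ns, ne = starts[nearest], ends[nearest]
    nstrand = strands[nearest]
    inside = d == 0
    d_tss = np.abs(positions - tss[nearest])
    d_tes = np.abs(positions - tes[nearest])
    side = np.where(inside,
                    np.where(d_tss <= d_tes, TSS, TES),
                    np.where(positions < ns,
                             np.where(nstrand == "+", TSS, TES),
                             np.where(nstrand == "+", TES, TSS)))
    offset = np.where(inside, np.minimum(d_tss, d_tes), -d).astype(np.int64)
    return side, offset, nearest


def _window_map_sums(ws: np.ndarray, we: np.ndarray, map_chrom: pd.DataFrame):
    """Per-window (sum of rate x overlap_bp, overlap_bp) against a sorted map."""
    s = map_chrom["start"].to_numpy(np.int64)
    e = map_chrom["end"].to_numpy(np.int64)
    r = map_chrom["rate"].to_numpy(float)
    seg_len = (e - s).astype(float)
    c_rate = np.concatenate(([0.0], np.cumsum(r * seg_len)))
    c_bp = np.concatenate(([0.0], np.cumsum(seg_len)))
    lo = np.searchsorted(e, ws, side="right")
    hi = np.searchsorted(s, we, side="left")
    any_overlap = hi > lo
    rate_sum = c_rate[hi] - c_rate[lo]
    bp = c_bp[hi] - c_bp[lo]
    lo_c = np.clip(lo, 0, s.size - 1)
    hi_c = np.clip(hi - 1, 0, s.size - 1)
    left_trim = np.where(any_overlap, np.maximum(ws - s[lo_c], 0), 0)
    right_trim = np.where(any_overlap, np.maximum(e[hi_c] - we, 0), 0)
    rate_sum -= left_trim * r[lo_c] + right_trim * r[hi_c]
    bp -= left_trim + right_trim
    rate_sum[~any_overlap] = 0.0
    bp[~any_overlap] = 0.0
    return rate_sum, bp


def recombination_profile(
    recmap: RecombinationMap,
    genes: pd.DataFrame,
    expression: pd.Series,
    n_classes: int = 3,
    bin_width: int = 1000,
    max_dist: int = 50000,
    window: int = 1000,
    *,
    layout: GenomeLayout,
) -> pd.DataFrame:
    """Mean recombination rate per (expression class, side, distance bin).

    Only genes with detectable expression (> 0) are kept and split into
    `n_classes` equal-sized classes by expression rank (class
    `n_classes` = most expressed). For each class the genome is scanned
    in fixed `window`-bp windows; each window midpoint is assigned a
    metagene coordinate against that class's genes, windows beyond
    `max_dist` are dropped, and per-bin means are map-coverage weighted:
    mean_rate = sum(rate x overlap_bp) / sum(overlap_bp).
    """
    if recmap.records.empty:
        raise ValueError("empty recombination map")
    if bin_width <= 0 or window <= 0 or max_dist <= 0:
        raise ValueError("bin_width, window and max_dist must be positive")
    expressed = genes[genes["gene_id"].map(expression).fillna(0.0) > 0].reset_index(drop=True)
    if len(expressed) < n_classes:
        raise ValueError(f"only {len(expressed)} detectably expressed genes for {n_classes} classes")
    values = expressed["gene_id"].map(expression).to_numpy(float)
    classes = rank_split(expressed["gene_id"].to_numpy(), values, n_classes)

    map_groups = {c: g for c, g in recmap.records.groupby("chrom", sort=False)}
    acc: dict[tuple, list[float]] = {}
    for chrom in layout.names:
        clen = layout.length_of(chrom)
        n_win = clen // window
        if n_win == 0 or chrom not in map_groups:
            continue
        ws = np.arange(n_win, dtype=np.int64) * window
        we = ws + window
        mid = ws + window // 2
        rate_sum, bp = _window_map_sums(ws, we, map_groups[chrom])
        for cls in range(1, n_classes + 1):
            members = expressed[classes.loc[expressed["gene_id"]].to_numpy() == cls]
            sub = members[members["chrom"] == chrom]
            if sub.empty:
                continue
            side, offset, _ = _coords_for_positions(mid, sub)
            keep = (offset >= -max_dist) & (offset < max_dist) & (bp > 0)
            bin_lo = (np.floor_divide(offset[keep], bin_width)) * bin_width
            for sd, blo, rs, b in zip(side[keep], bin_lo, rate_sum[keep], bp[keep]):
                key = (cls, sd, int(blo))
                slot = acc.setdefault(key, [0.0, 0.0])
                slot[0] += rs
                slot[1] += b
    rows = [
        {
            "expression_class": cls,
            "side": sd,
            "bin_lo": blo,
            "bin_hi": blo + bin_width,
            "mean_rate": rs / b,
            "covered_bp": int(b),
        }
        for (cls, sd, blo), (rs, b) in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["expression_class", "side", "bin_lo", "bin_hi",
                                       "mean_rate", "covered_bp"])
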