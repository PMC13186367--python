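"""Genome layout, interval arithmetic, callable masks and constrained shuffling.

All coordinates are 0-based, half-open (BED convention). Interval
collections are pandas DataFrames with at least the columns
``chrom`` (str), ``start`` (int) and ``end`` (int); an optional
``strand`` column holds ``+``, ``-`` or ``.``.

The one non-standard primitive here is :func:`shuffle_peaks`: a
constrained shuffle that relocates a peak set uniformly over all legal
placements inside a callable mask (genome minus blacklist minus long
zero-coverage runs), preserving the peak-length multiset exactly. It is
the null model behind the repeat-family enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


class GenomicInterval(NamedTuple):
    """A 0-based half-open span on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint base; floor of (start+end)/2 for even-length spans."""
        return (self.start + self.end) // 2


class GenomeLayout:
    """Ordered chromosome-name -> length (bp) mapping.

    Names must be unique and non-empty, lengths strictly positive.
    """

    def __init__(self, chromosomes: Mapping[str, int]):
        chroms: dict[str, int] = {}
        for name, length in chromosomes.items():
            if not isinstance(name, str) or not name:
                raise ValueError(f"chromosome name must be a non-empty string, got {name!r}")
            if name in chroms:
                raise ValueError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            chroms[name] = length
        if not chroms:
            raise ValueError("genome layout must contain at least one chromosome")
        self._chromosomes = chroms

    @property
    def chromosomes(self) -> dict[str, int]:
        return dict(self._chromosomes)

    @property
    def names(self) -> list[str]:
        return list(self._chromosomes)

    @property
    def total_length(self) -> int:
        return sum(self._chromosomes.values())

    def length_of(self, chrom: str) -> int:
        try:
            return self._chromosomes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chromosomes

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._chromosomes == other._chromosomes

    def __repr__(self) -> str:
        return f"GenomeLayout({self._chromosomes!r})"


def intervals_frame(records: Iterable[tuple] = (), strand: bool = False) -> pd.DataFrame:
    """Build an interval DataFrame from (chrom, start, end[, strand]) tuples."""
    cols = INTERVAL_COLUMNS + (["strand"] if strand else [])
    rows = [tuple(r)[: len(cols)] for r in records]
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64)})
        if strand:
            df["strand"] = pd.Series(dtype=str)
        return df
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def validate_intervals(df: pd.DataFrame, layout: GenomeLayout, what: str = "interval") -> pd.DataFrame:
    """Validate an interval frame against a layout; returns the frame.

    Raises ValueError naming the first offending record.
    """
    for col in INTERVAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{what} frame lacks required column {col!r}")
    if df.empty:
        return df
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if not (np.issubdtype(starts.dtype, np.integer) and np.issubdtype(ends.dtype, np.integer)):
        raise ValueError(f"{what} coordinates must be integers")
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in layout:
            i = sub.index[0]
            raise ValueError(f"{what} at index {i}: unknown chromosome {chrom!r}")
        clen = layout.length_of(chrom)
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        bad = (s < 0) | (s >= e) | (e > clen)
        if bad.any():
            i = sub.index[np.flatnonzero(bad)[0]]
            row = df.loc[i]
            raise ValueError(
                f"invalid {what} at index {i}: "
                f"({row['chrom']}, {row['start']}, {row['end']}) against length {clen}"
            )
    return df


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-or-unsorted arrays of intervals on one chromosome.

    Touching intervals (end == next start) are merged too, so the result
    is sorted, non-overlapping and non-adjacent.
    """
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    running_end = np.maximum.accumulate(e)
    new_group = np.empty(s.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = s[1:] > running_end[:-1]
    group_start_idx = np.flatnonzero(new_group)
    out_s = s[group_start_idx]
    out_e = np.empty_like(out_s)
    group_end_idx = np.append(group_start_idx[1:], s.size) - 1
    out_e[:] = running_end[group_end_idx]
    return out_s, out_e


def merge_intervals(df: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Sorted, merged (non-overlapping, non-adjacent) union of the input.

    The covered-base set is preserved exactly. Chromosomes are ordered by
    layout order when a layout is given, else lexicographically.
    """
    if layout is not None:
        validate_intervals(df, layout)
    if df.empty:
        return intervals_frame()
    chrom_order = layout.names if layout is not None else sorted(df["chrom"].unique())
    pieces = []
    groups = {c: g for c, g in df.groupby("chrom", sort=False)}
    for chrom in chrom_order:
        if chrom not in groups:
            continue
        g = groups[chrom]
        s, e = _merge_arrays(g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
        pieces.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    return pd.concat(pieces, ignore_index=True) if pieces else intervals_frame()


def complement(df: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Intervals covering exactly the bases the input does not cover."""
    merged = merge_intervals(df, layout)
    groups = {c: g for c, g in merged.groupby("chrom", sort=False)}
    pieces = []
    for chrom in layout.names:
        clen = layout.length_of(chrom)
        if chrom not in groups:
            pieces.append(pd.DataFrame({"chrom": [chrom], "start": [0], "end": [clen]}))
            continue
        g = groups[chrom]
        s = g["start"].to_numpy(np.int64)
        e = g["end"].to_numpy(np.int64)
        gap_s = np.concatenate(([0], e))
        gap_e = np.concatenate((s, [clen]))
        keep = gap_s < gap_e
        if keep.any():
            pieces.append(pd.DataFrame({"chrom": chrom, "start": gap_s[keep], "end": gap_e[keep]}))
    if not pieces:
        return intervals_frame()
    out = pd.concat(pieces, ignore_index=True)
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Base-wise intersection of two interval collections (each merged first)."""
    am = merge_intervals(a, layout)
    bm = merge_intervals(b, layout)
    pieces = []
    bg = {c: g for c, g in bm.groupby("chrom", sort=False)}
    for chrom, ga in am.groupby("chrom", sort=False):
        if chrom not in bg:
            continue
        gb = bg[chrom]
        as_, ae = ga["start"].to_numpy(), ga["end"].to_numpy()
        bs, be = gb["start"].to_numpy(), gb["end"].to_numpy()
        i = j = 0
        out_s, out_e = [], []
        while i < as_.size and j < bs.size:
            lo = max(as_[i], bs[j])
            hi = min(ae[i], be[j])
            if lo < hi:
                out_s.append(lo)
                out_e.append(hi)
            if ae[i] < be[j]:
                i += 1
            else:
                j += 1
        if out_s:
            pieces.append(pd.DataFrame({"chrom": chrom, "start": out_s, "end": out_e}))
    if not pieces:
        return intervals_frame()
    out = pd.concat(pieces, ignore_index=True)
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Bases of `a` not covered by `b`."""
    return intersect_intervals(a, complement(b, layout), layout)


def covered_bp(df: pd.DataFrame) -> int:
    """Total bases covered by a merged interval frame."""
    if df.empty:
        return 0
    return int((df["end"] - df["start"]).sum())


@dataclass(frozen=True)
class PeakSet:
    """A labelled collection of peak/event intervals (one event per row)."""

    label: str
    intervals: pd.DataFrame

    def __post_init__(self):
        if not self.label:
            raise ValueError("PeakSet label must be non-empty")

    @property
    def n(self) -> int:
        return len(self.intervals)

    def lengths(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy(np.int64)

    def centers(self) -> np.ndarray:
        s = self.intervals["start"].to_numpy(np.int64)
        e = self.intervals["end"].to_numpy(np.int64)
        return (s + e) // 2


@dataclass(frozen=True)
class CallableMask:
    """Merged, sorted per-chromosome segments where peaks can exist.

    The complement of (blacklist ∪ long zero-coverage runs): the only
    space where a peak caller could have seen a peak, hence the only
    space the shuffle null is allowed to place one.
    """

    layout: GenomeLayout
    segments: pd.DataFrame  # merged; columns chrom,start,end

    @property
    def total_bp(self) -> int:
        return covered_bp(self.segments)

    def segment_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(chrom array, start array, end array) over all segments."""
        return (self.segments["chrom"].to_numpy(),
                self.segments["start"].to_numpy(np.int64),
                self.segments["end"].to_numpy(np.int64))

    def contains_points(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Boolean per point: does the mask cover base `positions[i]` on `chroms[i]`?"""
        return points_in_intervals(chroms, positions, self.segments)


def points_in_intervals(chroms: Sequence[str], positions: np.ndarray, merged: pd.DataFrame) -> np.ndarray:
    """Membership of single bases in a merged interval frame (vectorised)."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    out = np.zeros(positions.size, dtype=bool)
    groups = {c: g for c, g in merged.groupby("chrom", sort=False)}
    for chrom in np.unique(chroms):
        if chrom not in groups:
            continue
        g = groups[chrom]
        s = g["start"].to_numpy(np.int64)
        e = g["end"].to_numpy(np.int64)
        sel = chroms == chrom
        p = positions[sel]
        idx = np.searchsorted(s, p, side="right") - 1
        ok = (idx >= 0) & (p < e[np.clip(idx, 0, e.size - 1)])
        out[sel] = ok
    return out


def build_callable_mask(
    layout: GenomeLayout,
    blacklist: pd.DataFrame,
    zero_coverage_runs: pd.DataFrame,
    min_zero_run: int = 1000,
) -> CallableMask:
    """Genome minus blacklist minus zero-coverage runs longer than `min_zero_run`.

    A zero-coverage run is excluded only when strictly longer than
    `min_zero_run` bp: short read gaps are still considered callable.
    """
    if min_zero_run < 0:
        raise ValueError("min_zero_run must be >= 0")
    validate_intervals(blacklist, layout, "blacklist")
    validate_intervals(zero_coverage_runs, layout, "zero-coverage run")
    if not zero_coverage_runs.empty:
        long_runs = zero_coverage_runs[
            (zero_coverage_runs["end"] - zero_coverage_runs["start"]) > min_zero_run
        ]
    else:
        long_runs = zero_coverage_runs
    excluded = pd.concat([blacklist[INTERVAL_COLUMNS] if not blacklist.empty else blacklist,
                          long_runs[INTERVAL_COLUMNS] if not long_runs.empty else long_runs],
                         ignore_index=True)
    if excluded.empty:
        excluded = intervals_frame()
    mask_df = complement(excluded, layout)
    if mask_df.empty:
        raise ValueError("callable mask is empty: blacklist and zero-coverage runs cover the genome")
    return CallableMask(layout=layout, segments=mask_df)


def window_around_center(interval: GenomicInterval, halfwidth: int, layout: GenomeLayout) -> GenomicInterval:
    """[center-halfwidth, center+halfwidth) clipped to the chromosome.

    halfwidth 0 degenerates to the 1-bp window [center, center+1) so that
    overlap stays well defined.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    clen = layout.length_of(interval.chrom)
    c = interval.center
    if halfwidth == 0:
        return GenomicInterval(interval.chrom, c, c + 1)
    return GenomicInterval(interval.chrom, max(0, c - halfwidth), min(clen, c + halfwidth))


def windows_around_centers(df: pd.DataFrame, halfwidth: int, layout: GenomeLayout) -> pd.DataFrame:
    """Vectorised :func:`window_around_center` over an interval frame."""
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if df.empty:
        return intervals_frame()
    c = (df["start"].to_numpy(np.int64) + df["end"].to_numpy(np.int64)) // 2
    clens = df["chrom"].map(layout.chromosomes).to_numpy(np.int64)
    if halfwidth == 0:
        ws, we = c, c + 1
    else:
        ws = np.maximum(0, c - halfwidth)
        we = np.minimum(clens, c + halfwidth)
    return pd.DataFrame({"chrom": df["chrom"].to_numpy(), "start": ws, "end": we})


def count_overlapping(queries: pd.DataFrame, targets: pd.DataFrame,
                      layout: GenomeLayout | None = None,
                      assume_merged: bool = False) -> tuple[int, np.ndarray]:
    """How many queries share >= 1 base with any target.

    Returns (count, per-query boolean indicator aligned with `queries`
    row order). `assume_merged` skips re-merging targets already known
    to be sorted and non-overlapping.
    """
    if layout is not None:
        validate_intervals(queries, layout, "query")
        validate_intervals(targets, layout, "target")
    hit = np.zeros(len(queries), dtype=bool)
    if queries.empty or targets.empty:
        return 0, hit
    merged = targets if assume_merged else merge_intervals(targets)
    tg = {c: g for c, g in merged.groupby("chrom", sort=False)}
    q = queries.reset_index(drop=True)
    for chrom, gq in q.groupby("chrom", sort=False):
        if chrom not in tg:
            continue
        g = tg[chrom]
        ts = g["start"].to_numpy(np.int64)
        te = g["end"].to_numpy(np.int64)
        qs = gq["start"].to_numpy(np.int64)
        qe = gq["end"].to_numpy(np.int64)
        # only the merged target with greatest start < query end can overlap
        idx = np.searchsorted(ts, qe, side="left") - 1
        ok = (idx >= 0) & (te[np.clip(idx, 0, te.size - 1)] > qs)
        hit[gq.index.to_numpy()] = ok
    return int(hit.sum()), hit


def uniform_placements(lengths: np.ndarray, mask: CallableMask,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Place one interval per requested length uniformly over all legal placements.

    A placement is legal when the interval lies entirely within a single
    mask segment. The segment is implicitly chosen with probability
    proportional to (segment_length - interval_length + 1), then the
    offset uniformly among valid starts — together exactly uniform over
    legal placements.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        return intervals_frame()
    if (lengths <= 0).any():
        raise ValueError("interval lengths must be positive")
    seg_chrom, seg_start, seg_end = mask.segment_arrays()
    seg_len = seg_end - seg_start
    # n_peaks x n_segments matrix of placement counts
    w = seg_len[None, :] - lengths[:, None] + 1
    np.clip(w, 0, None, out=w)
    total = w.sum(axis=1)
    if (total == 0).any():
        bad = int(np.flatnonzero(total == 0)[0])
        raise ValueError(
            f"peak {bad} of length {int(lengths[bad])} bp exceeds every callable segment "
            f"(longest segment: {int(seg_len.max())} bp)"
        )
    cw = np.cumsum(w, axis=1)
    t = rng.integers(0, total)  # per-row high
    seg_idx = (cw <= t[:, None]).sum(axis=1)
    prev = np.where(seg_idx > 0, np.take_along_axis(cw, np.maximum(seg_idx - 1, 0)[:, None], 1)[:, 0], 0)
    offset = t - prev
    starts = seg_start[seg_idx] + offset
    return pd.DataFrame({"chrom": seg_chrom[seg_idx], "start": starts, "end": starts + lengths})


def shuffle_peaks(peaks: PeakSet, mask: CallableMask, rng_seed: int | np.random.Generator) -> PeakSet:
    """Relocate every peak uniformly over legal placements inside the mask.

    Conserves the peak count and the multiset of peak lengths exactly;
    shuffled peaks may overlap one another and are not constrained to
    their chromosome of origin.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    placed = uniform_placements(peaks.lengths(), mask, rng)
    return PeakSet(label=peaks.label, intervals=placed)
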