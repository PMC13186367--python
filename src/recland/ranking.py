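"""Rank-based splitting of genes into near-equal expression groups."""

from __future__ import annotations

import numpy as np
import pandas as pd


def rank_split(ids, values, n_groups: int) -> pd.Series:
    """Split ids into `n_groups` near-equal groups by ascending value rank.

    Ties are broken by lexicographic id order so the split is fully
    deterministic. Returns a Series id -> group index in 1..n_groups
    (1 = lowest values). Group sizes differ by at most one; when the
    split is uneven the lower groups take the extra members.
    """
    ids = np.asarray(ids, dtype=object)
    values = np.asarray(values, dtype=float)
    if ids.size != values.size:
        raise ValueError("ids and values must have equal length")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if ids.size < n_groups:
        raise ValueError(f"cannot split {ids.size} genes into {n_groups} groups")
    order = np.lexsort((ids.astype(str), values))
    group = np.empty(ids.size, dtype=np.int64)
    for g, chunk in enumerate(np.array_split(np.arange(ids.size), n_groups), start=1):
        group[order[chunk]] = g
    return pd.Series(group, index=ids)
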