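import numpy as np
import pytest

from recland.core import GenomeLayout, intervals_frame


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def per_base_union(df, layout):
    """Brute-force boolean-array coverage per chromosome."""
    cover = {c: np.zeros(layout.length_of(c), dtype=bool) for c in layout.names}
    for row in df.itertuples(index=False):
        cover[row.chrom][row.start:row.end] = True
    return cover


def random_interval_frame(rng, layout, n, max_len=500):
    names = layout.names
    clens = np.array([layout.length_of(c) for c in names])
    ci = rng.integers(0, len(names), size=n)
    lengths = np.minimum(rng.integers(1, max_len + 1, size=n), clens[ci])
    starts = (rng.random(n) * (clens[ci] - lengths + 1)).astype(np.int64)
    return intervals_frame(
        [(names[c], int(s), int(s + L)) for c, s, L in zip(ci, starts, lengths)]
    )
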