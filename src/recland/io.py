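"""Readers and writers for the external formats the pipeline touches.

Supported on input: BED3/BED6, ENCODE narrowPeak, UCSC RepeatMasker
(rmsk) table rows, GTF 2.2 gene models, 4-column bedGraph recombination
maps, TSV expression tables, and two-column chromosome-size files. All
result tables are written as TSV. Files may be plain or gzip-compressed,
auto-detected by the ``.gz`` suffix.

Every reader validates coordinates against a declared
:class:`~recland.core.GenomeLayout` and rejects out-of-range records
rather than clipping them. GTF's 1-based inclusive coordinates are
converted to the internal 0-based half-open convention on read.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd

from .core import (
    GenomeLayout,
    PeakSet,
    intervals_frame,
    validate_intervals,
)

logger = logging.getLogger(__name__)

_DIALECT_MIN_COLS = {"BED3": 3, "BED6": 6, "narrowPeak": 10}

#: UCSC rmsk table columns this module requires.
RMSK_COLUMNS = ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily"]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _data_lines(handle: IO[str]) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/track lines."""
    for i, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(("#", "track", "browser")):
            continue
        yield i, line


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Two-column TSV (chromosome name, length in bp) -> GenomeLayout."""
    chroms: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in _data_lines(fh):
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            try:
                chroms[fields[0]] = int(fields[1])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer length {fields[1]!r}") from None
    return GenomeLayout(chroms)


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, length in layout.chromosomes.items():
            fh.write(f"{name}\t{length}\n")


def read_intervals(path: str | Path, layout: GenomeLayout, dialect: str = "BED3",
                   label: str | None = None) -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a PeakSet.

    Track/comment lines are skipped; the label defaults to the file stem.
    Malformed lines and out-of-layout coordinates raise ValueError with
    the offending line number.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECT_MIN_COLS)}")
    min_cols = _DIALECT_MIN_COLS[dialect]
    rows = []
    with _open_text(path) as fh:
        for lineno, line in _data_lines(fh):
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ValueError(
                    f"{path}: line {lineno}: {dialect} requires >= {min_cols} columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            strand = fields[5] if min_cols >= 6 else "."
            rows.append((fields[0], start, end, strand))
    df = intervals_frame(rows, strand=True)
    try:
        validate_intervals(df, layout, "peak")
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    if label is None:
        stem = Path(path).name
        for suffix in (".gz", ".bed", ".narrowPeak", ".txt"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        label = stem or "peaks"
    return PeakSet(label=label, intervals=df)


def write_intervals(df: pd.DataFrame, path: str | Path) -> None:
    """Write an interval frame as BED3 (or BED6 when strand+name present)."""
    with _open_text(path, "wt") as fh:
        has_strand = "strand" in df.columns
        for row in df.itertuples(index=False):
            if has_strand:
                name = getattr(row, "name", ".")
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n")
            else:
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


@dataclass(frozen=True)
class RepeatAnnotation:
    """Repeat elements tagged with a family label, plus read-filter counts."""

    records: pd.DataFrame  # columns chrom,start,end,family
    retained: int = 0
    dropped: int = 0

    @property
    def families(self) -> list[str]:
        return sorted(self.records["family"].unique())

    def family_frame(self, family: str) -> pd.DataFrame:
        return self.records[self.records["family"] == family]


def read_repeatmasker(path: str | Path, layout: GenomeLayout,
                      families: set[str] | list[str] | None,
                      key: str = "repFamily") -> RepeatAnnotation:
    """UCSC rmsk table -> RepeatAnnotation keeping only the requested families.

    `key` selects the grouping column: ``repFamily`` (default, matches
    family-level labels like MaLR/ERV1/MIR) or ``repClass``. With
    ``families=None`` every family in the table is kept.
    """
    if key not in ("repFamily", "repClass"):
        raise ValueError("key must be 'repFamily' or 'repClass'")
    with _open_text(path) as fh:
        table = pd.read_csv(fh, sep="\t")
    missing = [c for c in RMSK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: rmsk table missing column(s) {missing}")
    if families is None:
        keep = table[key].notna()
    else:
        keep = table[key].isin(set(families))
    retained = table[keep]
    df = pd.DataFrame({
        "chrom": retained["genoName"].to_numpy(),
        "start": retained["genoStart"].to_numpy(np.int64),
        "end": retained["genoEnd"].to_numpy(np.int64),
        "family": retained[key].to_numpy(),
    }).reset_index(drop=True)
    validate_intervals(df, layout, "repeat")
    n_kept, n_dropped = int(keep.sum()), int((~keep).sum())
    logger.info("read_repeatmasker: retained %d records, dropped %d", n_kept, n_dropped)
    return RepeatAnnotation(records=df, retained=n_kept, dropped=n_dropped)


def write_repeatmasker(records: pd.DataFrame, path: str | Path) -> None:
    """Write repeat records in the rmsk table layout this module reads back."""
    out = pd.DataFrame({
        "genoName": records["chrom"],
        "genoStart": records["start"],
        "genoEnd": records["end"],
        "strand": records.get("strand", pd.Series(["+"] * len(records))),
        "repName": records["family"] + "-elt",
        "repClass": records["family"],
        "repFamily": records["family"],
    })
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def read_genes_gtf(path: str | Path, layout: GenomeLayout) -> pd.DataFrame:
    """GTF gene/transcript records -> one gene model per gene_id.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand,
    tss, tes (0-based half-open span; TSS/TES strand-oriented: for a
    ``-`` strand gene the TSS is the last base of the span). When a gene
    has several transcripts the span is their outer envelope.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True, disable_infer_transcripts=True)
    spans: dict[str, list] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "transcript", "mRNA"):
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ValueError(f"{path}: {feat.featuretype} record without gene_id at "
                             f"{feat.seqid}:{feat.start}-{feat.end}")
        if feat.strand not in ("+", "-"):
            raise ValueError(f"{path}: gene {gid!r} has strand {feat.strand!r}; "
                             "TSS/TES are undefined without orientation")
        start0 = feat.start - 1  # GTF is 1-based inclusive
        end0 = feat.end
        if gid in spans:
            prev = spans[gid]
            if prev[0] != feat.seqid or prev[3] != feat.strand:
                raise ValueError(f"{path}: gene {gid!r} spans multiple chromosomes or strands")
            prev[1] = min(prev[1], start0)
            prev[2] = max(prev[2], end0)
        else:
            spans[gid] = [feat.seqid, start0, end0, feat.strand]
    if not spans:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand", "tss", "tes"])
    rows = [(gid, c, s, e, st) for gid, (c, s, e, st) in spans.items()]
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes = genes.sort_values(["chrom", "start", "gene_id"], kind="mergesort").reset_index(drop=True)
    validate_intervals(genes, layout, "gene")
    return add_tss_tes(genes)


def add_tss_tes(genes: pd.DataFrame) -> pd.DataFrame:
    """Derive strand-oriented TSS/TES columns from span + strand."""
    genes = genes.copy()
    plus = genes["strand"] == "+"
    genes["tss"] = np.where(plus, genes["start"], genes["end"] - 1).astype(np.int64)
    genes["tes"] = np.where(plus, genes["end"] - 1, genes["start"]).astype(np.int64)
    return genes


def write_genes_gtf(genes: pd.DataFrame, path: str | Path, source: str = "recland") -> None:
    """Write gene models as GTF gene records (1-based inclusive on disk)."""
    with _open_text(path, "wt") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n")


@dataclass(frozen=True)
class RecombinationMap:
    """Non-overlapping intervals with a recombination rate (cM/Mb each)."""

    records: pd.DataFrame  # columns chrom,start,end,rate; sorted per chrom

    def mean_rate(self) -> float:
        """Length-weighted mean rate over the covered bases."""
        lengths = (self.records["end"] - self.records["start"]).to_numpy()
        return float((self.records["rate"].to_numpy() * lengths).sum() / lengths.sum())


def validate_recmap(df: pd.DataFrame, layout: GenomeLayout) -> RecombinationMap:
    validate_intervals(df, layout, "recombination-map record")
    if (df["rate"] < 0).any():
        i = df.index[df["rate"] < 0][0]
        raise ValueError(f"negative recombination rate at index {i}")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    for chrom, g in df.groupby("chrom", sort=False):
        s = g["start"].to_numpy()
        e = g["end"].to_numpy()
        if (s[1:] < e[:-1]).any():
            raise ValueError(f"overlapping recombination-map records on {chrom}: rate is ambiguous")
    return RecombinationMap(records=df)


def read_recmap_bedgraph(path: str | Path, layout: GenomeLayout) -> RecombinationMap:
    """4-column bedGraph (chrom, start, end, rate) -> RecombinationMap."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in _data_lines(fh):
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: bedGraph requires 4 columns")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: malformed bedGraph record") from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rate"])
    if df.empty:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64), "rate": pd.Series(dtype=float)})
        return RecombinationMap(records=df)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    try:
        return validate_recmap(df, layout)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_recmap_bedgraph(recmap: RecombinationMap, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for row in recmap.records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{_fmt(row.rate)}\n")


def read_expression_tsv(path: str | Path, gene_col: str | None = None,
                        value_col: str | None = None) -> pd.Series:
    """TSV with header -> Series gene_id -> expression value.

    Defaults to the first column as gene id and the second as value.
    Duplicate ids and non-numeric or negative values are errors.
    """
    with _open_text(path) as fh:
        table = pd.read_csv(fh, sep="\t")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expression table needs >= 2 columns")
    gene_col = gene_col or table.columns[0]
    value_col = value_col or table.columns[1]
    for col in (gene_col, value_col):
        if col not in table.columns:
            raise ValueError(f"{path}: no column named {col!r}")
    ids = table[gene_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    values = pd.to_numeric(table[value_col], errors="coerce")
    if values.isna().any():
        i = values.index[values.isna()][0]
        raise ValueError(f"{path}: non-numeric expression value for gene {ids.iloc[i]!r}")
    if (values < 0).any():
        i = values.index[values < 0][0]
        raise ValueError(f"{path}: negative expression value for gene {ids.iloc[i]!r}")
    return pd.Series(values.to_numpy(float), index=ids.to_numpy(), name=value_col)


def write_expression_tsv(expression: pd.Series, path: str | Path,
                         gene_col: str = "gene_id", value_col: str = "expression") -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"{gene_col}\t{value_col}\n")
        for gid in sorted(expression.index):
            fh.write(f"{gid}\t{_fmt(expression[gid])}\n")


def _fmt(x) -> str:
    """Fixed float formatting: 6 significant digits, integers untouched."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    if isinstance(x, float) and np.isinf(x):
        return "inf"
    return f"{x:.6g}"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV writer for result tables.

    Rows are sorted lexicographically over all columns (stable), floats
    are formatted at 6 significant digits, header always present.
    """
    out = df.sort_values(by=list(df.columns), kind="mergesort") if len(df) else df
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(map(str, out.columns)) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_fmt(v) if isinstance(v, (float, np.floating)) else str(v)
                               for v in row) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])
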