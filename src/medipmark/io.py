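"""Readers and writers for the pipeline's plain-text interchange formats.

All tabular data is TSV with a header line; genomic intervals go to BED
(0-based half-open, no header); evidence gene lists are one id per line with
``#`` comments. Every writer's output is re-readable by the matching reader
without loss (floats round-trip via shortest-repr formatting).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

PROBE_COLUMNS = ("probe_id", "chrom", "start", "end", "log2_ratio")


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t")


def read_probe_table(path) -> pd.DataFrame:
    """Read, validate, and sort a tiling probe table.

    Requires columns probe_id, chrom, start, end, log2_ratio; asserts
    start < end per row (errors name the file line, header = line 1).
    """
    df = _read_tsv(path)
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce")
    bad = df.index[ratios.isna()]
    if len(bad):
        raise InputError(f"{path}: non-numeric log2_ratio at line {bad[0] + 2}")
    df["log2_ratio"] = ratios
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise InputError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
        df[col] = vals.astype(int)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise InputError(f"{path}: start >= end at line {bad[0] + 2}")
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return df[list(PROBE_COLUMNS) + [c for c in df.columns if c not in PROBE_COLUMNS]]


def write_probe_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_promoters_bed(path) -> pd.DataFrame:
    """Read a promoter annotation BED (>= 4 columns; name = gene id)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputError(f"{path}: line {lineno}: need >= 4 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise InputError(f"{path}: line {lineno}: non-integer coordinates")
            if start >= end:
                raise InputError(f"{path}: line {lineno}: start >= end")
            rows.append((parts[0], start, end, parts[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def write_promoters_bed(promoters: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in promoters.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t0\t.\n")


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write called regions as 6-column BED.

    name = gene id when annotated else region_<i>; score = round(100 x
    peak_score) capped at 1000; strand '.'. BED has no header, so an empty
    region list produces an empty file.
    """
    with open(path, "w") as fh:
        for i, r in enumerate(regions.itertuples(index=False)):
            name = getattr(r, "gene", None) or f"region_{i}"
            score = min(1000, int(round(100 * r.peak_score)))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t.\n")


def read_gene_list(path) -> set[str]:
    """Plain-text gene list: one id per line, '#' comments and blanks allowed."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    genes = set()
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                genes.add(entry)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_pool_matrix(path) -> pd.DataFrame:
    """Pooled-MSP ordinal matrix: rows = genes, columns = 'group:pool' labels."""
    df = _read_tsv(path)
    if df.columns[0] != "gene":
        raise InputError(f"{path}: first column must be 'gene'")
    df = df.set_index("gene")
    try:
        df = df.astype(int)
    except ValueError:
        raise InputError(f"{path}: pool matrix entries must be integers 0..4")
    return df


def write_pool_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_reexpression(path) -> pd.DataFrame:
    """Cell-line re-expression records: gene, cell_line, fold_change."""
    df = _read_tsv(path)
    need = ["gene", "cell_line", "fold_change"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    df["fold_change"] = pd.to_numeric(df["fold_change"], errors="raise")
    return df[need]


def read_cp_table(path) -> pd.DataFrame:
    """QMSP Cp table: sample_id, grade, cp_ref, cp_gene (missing Cp = empty)."""
    df = _read_tsv(path)
    need = ["sample_id", "grade", "cp_ref", "cp_gene"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    for col in ("cp_ref", "cp_gene"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[need]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_regions_bed(path) -> pd.DataFrame:
    """Re-read a regions BED written by :func:`write_regions_bed`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start, end, name, score, strand = line.split("\t")
            rows.append((chrom, int(start), int(end), name, int(score) / 100.0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "peak_score"])
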