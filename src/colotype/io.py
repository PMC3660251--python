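"""Readers and writers for the pipeline's tabular formats.

Expression matrices as TSV (genes x samples, header row) or GCT 1.2;
sample annotations as CSV; copy-number profiles as SEG-like TSV
(sample, chrom, start, end, state or log2-ratio; 1-based inclusive
coordinates per the SEG convention); gene sets as GMT.  All tables are
written as TSV with the literal NA token for missing values.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import CGHCohort

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

#: log2-ratio magnitude above which a segment is called gained/lost when a
#: SEG file carries continuous values.
SEG_RATIO_THRESHOLD = 0.1


class ParseError(ValueError):
    """A malformed input file."""


def _validate_expression(df: pd.DataFrame, path) -> pd.DataFrame:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()[:5]
        raise ParseError(f"{path}: duplicate gene identifiers {list(dups)}")
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate sample identifiers")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        for i, (_, row) in enumerate(df.iterrows(), start=2):
            if pd.to_numeric(row, errors="coerce").isna().any():
                raise ParseError(
                    f"{path}: non-numeric value on line {i}") from exc
        raise ParseError(f"{path}: non-numeric values") from exc
    if not np.isfinite(values.to_numpy()).all():
        raise ParseError(f"{path}: non-finite expression values")
    return values


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log2 expression matrix (TSV or GCT 1.2)."""
    path = Path(path)
    if path.suffix.lower() == ".gct":
        return _read_gct(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return _validate_expression(df, path)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}: expected GCT version '#1.2', "
                             f"got {version!r} on line 1")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ParseError(f"{path}: malformed dimensions on line 2")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    if body.shape[0] != n_genes or body.shape[1] - 2 != n_samples:
        raise ParseError(
            f"{path}: header declares {n_genes} x {n_samples} but body is "
            f"{body.shape[0]} x {body.shape[1] - 2}")
    body = body.set_index(body.columns[0]).drop(columns=body.columns[1])
    body.index.name = "gene_id"
    return _validate_expression(body, path)


def write_expression(expr: pd.DataFrame, path, fmt: str | None = None
                     ) -> None:
    path = Path(path)
    fmt = fmt or ("gct" if path.suffix.lower() == ".gct" else "tsv")
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            out = expr.copy()
            out.insert(0, "Description", expr.index)
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", na_rep=NA_TOKEN)
    else:
        expr.to_csv(path, sep="\t", na_rep=NA_TOKEN,
                    index_label="gene_id")


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, na_values=[NA_TOKEN])


def write_annotations(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, na_rep=NA_TOKEN, index_label="sample_id")


def write_seg(cohort: CGHCohort, path) -> None:
    """Write arm-level states in SEG-like TSV (one row per sample x bin)."""
    rows = []
    for sid in cohort.sample_ids:
        states = cohort.states[sid]
        for b, st in states.items():
            bin_row = cohort.bins.loc[b]
            rows.append((sid, bin_row["chrom"], bin_row["start"],
                         bin_row["end"], st))
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "state"]
                 ).to_csv(path, sep="\t", index=False)


def read_seg(path, ratio_threshold: float = SEG_RATIO_THRESHOLD
             ) -> CGHCohort:
    """Read a SEG-like TSV into a cohort of per-bin states.

    The value column may be a discrete state (-1/0/1) or a continuous
    log2 ratio, in which case segments beyond ±``ratio_threshold`` are
    called as gain/loss.  All samples must share one segmentation.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns "
                         f"{sorted(required - set(df.columns))}")
    value_col = df.columns[-1]
    grids = df.groupby("sample")[["chrom", "start", "end"]].apply(
        lambda g: tuple(map(tuple, g.to_numpy())))
    if grids.nunique() != 1:
        raise ParseError(f"{path}: samples have differing segmentations; "
                         "a shared bin grid is required")
    first = df[df["sample"] == df["sample"].iloc[0]]
    bins = first[["chrom", "start", "end"]].copy()
    bins["chrom"] = bins["chrom"].astype(str)
    bins["length"] = bins["end"] - bins["start"] + 1
    bins.index = [f"{c}:{s}-{e}" for c, s, e in
                  zip(bins["chrom"], bins["start"], bins["end"])]
    v = df[value_col].astype(float)
    if set(np.unique(v)) <= {-1.0, 0.0, 1.0}:
        states = v.astype(int)
    else:
        states = pd.Series(np.sign(v).astype(int)
                           * (v.abs() > ratio_threshold).astype(int))
    mat = pd.DataFrame(
        states.to_numpy().reshape(df["sample"].nunique(), len(bins)).T,
        index=bins.index, columns=pd.unique(df["sample"]))
    return CGHCohort(bins=bins, states=mat)


def read_gmt(path) -> dict[str, set]:
    """Read gene sets from GMT (name, description, genes...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {i} has fewer than 3 fields")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name, *sorted(genes)]) + "\n")


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=index)
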