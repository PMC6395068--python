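"""Readers and writers for expression matrices, designs, GMT files and
results tables.

All tabular formats are plain text. Readers reject malformed input with an
error naming the offending location; there is no silent coercion and NA
tokens are hard errors.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from factorde.types import (
    DEFAULT_DURATIONS,
    FACTOR_LEVELS,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    SampleDesign,
    ValidationError,
)

GENE_ID_HEADER = "gene_id"
_NA_TOKENS = {"", "na", "nan", "null", "none", "n/a"}

# 12 significant digits: round-trips doubles to well under 1e-9 on the
# magnitudes this pipeline produces.
_FLOAT_FMT = "%.12g"


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited gene-by-sample matrix.

    First header token must be ``gene_id`` (guards against transposed
    files); remaining header tokens are sample identifiers; each data row is
    a gene identifier followed by numeric log2 intensities.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != GENE_ID_HEADER:
            raise FormatError(
                f"{path}: first header field must be {GENE_ID_HEADER!r} "
                f"(got {header[0]!r}); is the matrix transposed?"
            )
        sample_ids = header[1:]
        if not sample_ids:
            raise FormatError(f"{path}: no sample columns in header")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(fields)}"
                )
            gene_ids.append(fields[0])
            row = []
            for col, cell in enumerate(fields[1:], start=2):
                if cell.strip().lower() in _NA_TOKENS:
                    raise FormatError(
                        f"{path}:{lineno}: missing value in column {col} "
                        f"(sample {sample_ids[col - 2]!r}); NA is not supported"
                    )
                try:
                    v = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in "
                        f"column {col} (sample {sample_ids[col - 2]!r})"
                    ) from None
                if not math.isfinite(v):
                    raise FormatError(
                        f"{path}:{lineno}: non-finite value {cell!r} in column {col}"
                    )
                row.append(v)
            rows.append(row)
    try:
        return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))
    except ValidationError as e:
        raise FormatError(f"{path}: {e}") from e


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join([GENE_ID_HEADER, *expr.sample_ids]) + "\n")
        for gene, row in zip(expr.gene_ids, expr.values):
            fh.write(gene + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


_DESIGN_COLUMNS = ("sample_id", "exposure", "genotype", "sex", "duration_days")


def read_design(
    path: str | Path,
    allowed_durations: tuple[int, ...] = DEFAULT_DURATIONS,
) -> SampleDesign:
    """Read a tab- or comma-delimited design table.

    Requires columns sample_id, exposure, genotype, sex, duration_days.
    Unknown factor levels and durations outside `allowed_durations`
    (default {1, 5}) are validation errors.
    """
    path = Path(path)
    sep = "\t"
    with path.open() as fh:
        first = fh.readline()
    if "," in first and "\t" not in first:
        sep = ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    try:
        durations = [int(d) for d in df["duration_days"]]
    except ValueError as e:
        raise FormatError(f"{path}: non-integer duration_days value: {e}") from None
    try:
        return SampleDesign(
            list(df["sample_id"]),
            list(df["exposure"]),
            list(df["genotype"]),
            list(df["sex"]),
            durations,
            allowed_durations,
        )
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


def write_design(design: SampleDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": design.sample_ids,
            "exposure": design.exposure,
            "genotype": design.genotype,
            "sex": design.sex,
            "duration_days": design.duration_days,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: one set per line — name, description, members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description and at least one member"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, list(universe) if universe else None)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_results_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any results DataFrame (effect/interaction/GSA/enrichment) as
    TSV, index included when named, floats at 12 significant digits."""
    index = table.index.name is not None
    table.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_results_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        df = df.set_index(index_col)
    return df
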