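"""Readers and writers for expression matrices, sample sheets and result tables.

Tabular outputs are TSV with ``#``-prefixed metadata comment lines (tool
version, seed, configuration hash); missing values are written as ``NA``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import ConcentrationDesign
from .filtering import GeneProfile

__all__ = [
    "read_expression",
    "profiles_from_matrix",
    "design_from_sheet",
    "write_table",
    "read_table",
    "config_hash",
]


def read_expression(matrix_path, sheet_path) -> tuple:
    """Read and validate an expression matrix and its sample sheet.

    The matrix is CSV/TSV with the gene identifier in the first column and
    one column per sample; the sheet has columns ``sample`` and
    ``concentration``.  Returns ``(matrix, concentrations)`` where ``matrix``
    is a genes x samples DataFrame indexed by gene id and ``concentrations``
    is a Series aligned to the matrix columns.

    Raises ``ValueError`` naming the offending sample / gene on mismatched
    samples, non-numeric cells or duplicate gene ids.
    """
    matrix = _read_any(matrix_path)
    sheet = _read_any(sheet_path)
    gene_col = matrix.columns[0]
    matrix = matrix.set_index(gene_col)
    matrix.index = matrix.index.astype(str)
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in matrix: {dups[:5]}")
    if not {"sample", "concentration"} <= set(sheet.columns):
        raise ValueError("sample sheet must have columns 'sample' and 'concentration'")
    sheet_samples = sheet["sample"].astype(str).tolist()
    matrix_samples = [str(c) for c in matrix.columns]
    missing_in_sheet = sorted(set(matrix_samples) - set(sheet_samples))
    if missing_in_sheet:
        raise ValueError(f"samples absent from sheet: {missing_in_sheet}")
    missing_in_matrix = sorted(set(sheet_samples) - set(matrix_samples))
    if missing_in_matrix:
        raise ValueError(f"samples absent from matrix: {missing_in_matrix}")
    try:
        matrix = matrix.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values: {exc}") from exc
    conc = pd.Series(
        sheet.set_index(sheet["sample"].astype(str))["concentration"].astype(float),
    ).reindex(matrix_samples)
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    return matrix, conc


def _read_any(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, comment="#")


def profiles_from_matrix(matrix: pd.DataFrame, conc: pd.Series) -> list:
    """Group each gene's samples by concentration into GeneProfile objects."""
    groups_by_conc = {
        float(c): [s for s in matrix.columns if conc[s] == c]
        for c in sorted(conc.unique())
    }
    profiles = []
    for gene, row in matrix.iterrows():
        profiles.append(
            GeneProfile(
                gene_id=str(gene),
                group_values={
                    c: row[cols].to_numpy(dtype=float)
                    for c, cols in groups_by_conc.items()
                },
            )
        )
    return profiles


def design_from_sheet(conc: pd.Series) -> ConcentrationDesign:
    levels = sorted(conc.unique())
    reps = [int((conc == c).sum()) for c in levels]
    return ConcentrationDesign(tuple(levels), tuple(reps))


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for output metadata."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a TSV with '#'-prefixed metadata lines and NA for missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    from . import __version__

    meta = {"tool": f"ec50shrink {__version__}"}
    meta.update(metadata or {})
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values="NA")
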