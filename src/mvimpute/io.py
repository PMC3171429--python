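"""Reading and writing expression matrices, configs and result tables.

The on-disk matrix dialect is plain tab-separated text: first row holds
sample identifiers, first column gene identifiers, and missing entries are
the literal, case-sensitive token ``NA``.  Internally missingness lives only
in the :class:`~mvimpute.types.MissingMask`; masked cells are stored as a 0.0
placeholder that consumers must never read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    RESULT_FIELDS,
    ExpressionMatrix,
    MissingMask,
    ResultRecord,
    SimulationParameters,
    check_aligned,
)

logger = logging.getLogger("mvimpute")

NA_TOKEN = "NA"


def read_matrix(path: str | Path) -> tuple[ExpressionMatrix, MissingMask]:
    """Read a genes x samples TSV with ``NA`` for missing entries.

    Returns the matrix (masked cells hold a 0.0 placeholder) and its mask.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: data region is empty")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ValueError(f"{path}: no sample columns")
    n_cols = len(sample_ids)
    gene_ids: list[str] = []
    values = np.zeros((len(lines) - 1, n_cols))
    flags = np.zeros((len(lines) - 1, n_cols), dtype=bool)
    for i, line in enumerate(lines[1:]):
        cells = line.split("\t")
        if len(cells) != n_cols + 1:
            raise ValueError(
                f"{path}: row {i + 2} has {len(cells) - 1} data cells, "
                f"expected {n_cols}")
        gene_ids.append(cells[0])
        for j, cell in enumerate(cells[1:]):
            if cell == NA_TOKEN:
                flags[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {i + 2}, "
                        f"column {j + 2}: {cell!r}") from None
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError(f"{path}: duplicate gene ids")
    return ExpressionMatrix(values, gene_ids, sample_ids), MissingMask(flags)


def write_matrix(matrix: ExpressionMatrix, mask: MissingMask | None,
                 path: str | Path) -> None:
    """Write a matrix as TSV, with masked cells as ``NA``.

    Numeric cells are printed with 10 significant digits (repr-faithful for
    round-tripping at that precision).
    """
    if mask is None:
        mask = MissingMask.empty(matrix.shape)
    check_aligned(matrix, mask)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["gene_id", *matrix.sample_ids]) + "\n")
        for i, gid in enumerate(matrix.gene_ids):
            cells = [gid]
            for j in range(matrix.shape[1]):
                if mask.flags[i, j]:
                    cells.append(NA_TOKEN)
                else:
                    cells.append(format(matrix.values[i, j], ".10g"))
            fh.write("\t".join(cells) + "\n")


def write_labels(labels, sample_ids: Sequence[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(sample_ids, labels.labels):
            fh.write(f"{sid}\t{lab}\n")


def write_results(records: Iterable[ResultRecord], path: str | Path,
                  append: bool = False) -> None:
    """Append-friendly long-format TSV of result records."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    write_header = not (append and path.exists() and path.stat().st_size > 0)
    mode = "a" if append else "w"
    with path.open(mode) as fh:
        if write_header:
            fh.write("\t".join(RESULT_FIELDS) + "\n")
        for rec in records:
            fh.write("\t".join(str(c) for c in rec.to_row()) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back as a DataFrame with typed columns."""
    df = pd.read_csv(path, sep="\t")
    missing = set(RESULT_FIELDS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing result columns {sorted(missing)}")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML config; top level must be a mapping."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return cfg


def load_params(path: str | Path) -> SimulationParameters:
    """Load SimulationParameters from YAML; unknown keys are an error."""
    return SimulationParameters.from_dict(load_config(path))


def log_params(params: SimulationParameters) -> None:
    logger.info("simulation parameters: %s", params.to_dict())
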