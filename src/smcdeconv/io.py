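"""Reading and writing expression matrices and run metadata.

The on-disk matrix dialect is tab-separated text: a header row of sample ids
whose first field is ``gene_id``, one row per gene.  CSV input is accepted by
sniffing the delimiter.  Values round-trip at full float precision.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ExpressionMatrix

__all__ = ["read_expression_matrix", "write_matrix", "write_run_metadata"]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression_matrix(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    """Parse a genes x samples TSV/CSV matrix.

    First column holds gene ids, the header row sample ids.  Ragged rows,
    non-numeric cells and duplicate ids are rejected with the offending
    location named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such matrix file: {path}")
    sep = {"tsv": "\t", "csv": ","}.get(dialect, None) or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    values = np.empty(df.shape, dtype=float)
    for cj, col in enumerate(df.columns):
        try:
            values[:, cj] = np.array([float(x) for x in df[col]])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell at gene {bad.index[0]!r}, sample {col!r} in {path}"
            ) from None
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
    )


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the TSV dialect at full (17 significant digit) precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def write_run_metadata(result, diagnostics, config, path: str | Path) -> None:
    """Structured YAML record of a run: seed, schedule, ESS trace, mapping, etc."""
    record = {
        "seed": config.seed,
        "config": asdict(config),
        "schedule": [float(e) for e in diagnostics.eps_used.eps]
        if diagnostics.eps_used is not None else None,
        "ess_trace": [float(e) for e in diagnostics.ess_trace],
        "resample_events": [int(t) for t in diagnostics.resample_events],
        "final_log_weight_spread": float(diagnostics.final_log_weight_spread),
        "lambda_hat": float(result.lambda_hat),
        "lambda_sd": float(result.lambda_sd),
        "mapping": list(result.mapping),
        "n_clamped_proportions": int(result.n_clamped),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)
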