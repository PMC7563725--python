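"""Reading and writing the pipeline's text formats.

Expression matrices travel as delimiter-autodetected TSV/CSV with gene
symbols in the first column and sample ids in the header; sample metadata is
a second table with ``sample``, ``batch`` and ``phenotype`` columns. Ground
truth from the synthetic generator round-trips through a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError
from .synthetic import GroundTruth

__all__ = [
    "read_expression",
    "write_expression",
    "write_ground_truth",
    "read_ground_truth",
    "write_table",
]


def _read_delimited(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.empty:
        raise ValidationError(f"{path}: empty table")
    return df


def read_expression(expr_path, meta_path) -> ExpressionMatrix:
    """Parse an expression table and its sample metadata into one object."""
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    df = _read_delimited(expr_path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise ValidationError(
            f"{expr_path}: non-numeric value at gene {gene!r}, sample {col!r}: "
            f"{df.loc[gene, col]!r}"
        )
    if numeric.isna().any().any():
        raise ValidationError(f"{expr_path}: missing values present")

    meta = pd.read_csv(meta_path, sep=None, engine="python")
    required = {"sample", "batch", "phenotype"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"{meta_path}: metadata needs columns {sorted(required)}, "
            f"got {list(meta.columns)}"
        )
    meta = meta.set_index("sample")
    missing = [s for s in numeric.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"samples missing metadata: {missing}")
    meta = meta.loc[numeric.columns]
    return ExpressionMatrix(
        numeric,
        meta["batch"].astype(str),
        meta["phenotype"].astype(int),
    )


def write_expression(matrix: ExpressionMatrix, expr_path, meta_path) -> None:
    """Write the expression TSV and metadata TSV accepted by read_expression."""
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    expr_path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(expr_path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {
            "sample": matrix.sample_ids,
            "batch": matrix.batch.values,
            "phenotype": matrix.phenotype.values,
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "module_assignment": truth.module_assignment.to_dict(),
        "de_genes": truth.de_genes,
        "hub_genes": truth.hub_genes,
        "batch_params": {
            b: {k: np.asarray(v).tolist() for k, v in d.items()}
            for b, d in truth.batch_params.items()
        },
    }
    path.write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        module_assignment=pd.Series(data["module_assignment"], name="module"),
        de_genes={g: float(v) for g, v in data["de_genes"].items()},
        hub_genes=data["hub_genes"],
        batch_params={
            b: {k: np.asarray(v) for k, v in d.items()}
            for b, d in data["batch_params"].items()
        },
    )


def write_table(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write any result table as TSV (utility shared by the pipeline stages)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label=index_label)
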