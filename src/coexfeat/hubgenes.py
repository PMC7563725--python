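"""Hub-gene mining in the key co-expression module.

Three per-gene statistics drive the screen:

* gene significance ``GS = |cor(gene expression, phenotype)|``,
* module membership ``MM`` — the *signed* correlation between a gene and its
  module's eigengene (so anti-correlated genes carry negative MM; screening
  uses the magnitude),
* intramodular connectivity ``K.in`` — the sum of a gene's network
  adjacencies to the other genes of its own module.

Hubs are the genes of the key module with GS above a floor, |MM| above a
floor, membership in the differential-expression screen, ranked by K.in
descending; the top ``top_n`` survive. Because correlations are invariant to
per-gene affine rescaling, GS and MM are identical whether computed on the
corrected or the standardized matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError
from .network import GREY

__all__ = [
    "gene_significance",
    "signed_kme",
    "intramodular_connectivity",
    "build_hub_table",
    "screen_hubs",
]

logger = logging.getLogger(__name__)


def gene_significance(matrix: ExpressionMatrix) -> pd.Series:
    """|Pearson r| between each gene and the 0/1 phenotype; constant genes get 0."""
    y = matrix.phenotype.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("phenotype must contain both classes")
    x = matrix.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    n_const = int((sx == 0).sum())
    if n_const:
        logger.warning("%d constant genes: GS set to 0", n_const)
    gs = np.abs(np.where(sx > 0, r, 0.0))
    return pd.Series(gs, index=matrix.gene_ids, name="GS")


def signed_kme(
    matrix: ExpressionMatrix, me: pd.DataFrame, labels: pd.Series
) -> pd.Series:
    """Signed correlation of each gene with its own module's eigengene.

    Grey (unassigned) genes get NaN.
    """
    labels = labels.reindex(matrix.gene_ids)
    mm = pd.Series(np.nan, index=matrix.gene_ids, name="MM")
    for mod in [m for m in labels.unique() if m != GREY]:
        key = f"ME{mod}"
        if key not in me.index:
            raise ValidationError(f"no eigengene for module {mod!r}")
        e = me.loc[key].to_numpy(dtype=float)
        genes = labels.index[labels == mod]
        x = matrix.values.loc[genes].to_numpy(dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        ec = e - e.mean()
        denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((ec**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ ec) / denom
        mm.loc[genes] = r
    return mm


def intramodular_connectivity(
    adjacency: pd.DataFrame, labels: pd.Series
) -> pd.Series:
    """K.in: sum of adjacencies to same-module genes (self excluded)."""
    labels = labels.reindex(adjacency.index)
    if labels.isna().any():
        raise ValidationError("labels do not cover all genes in the adjacency")
    a = adjacency.to_numpy(dtype=float)
    kin = np.zeros(len(labels))
    lab_arr = labels.to_numpy()
    for mod in pd.unique(lab_arr):
        idx = np.nonzero(lab_arr == mod)[0]
        sub = a[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        kin[idx] = sub.sum(axis=1)
    return pd.Series(kin, index=adjacency.index, name="K.in")


def build_hub_table(
    matrix: ExpressionMatrix,
    adjacency: pd.DataFrame,
    me: pd.DataFrame,
    labels: pd.Series,
    de_result: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-gene screening table (GS, MM, K.in, logFC, adj.p)."""
    gs = gene_significance(matrix)
    mm = signed_kme(matrix, me, labels)
    kin = intramodular_connectivity(adjacency, labels)
    table = pd.DataFrame(
        {
            "module": labels.reindex(matrix.gene_ids),
            "GS": gs,
            "MM": mm,
            "K.in": kin.reindex(matrix.gene_ids),
        }
    )
    table["logFC"] = de_result["logFC"].reindex(matrix.gene_ids)
    table["adj.P.Val"] = de_result["adj.P.Val"].reindex(matrix.gene_ids)
    return table


def screen_hubs(
    table: pd.DataFrame,
    de_genes,
    gs_min: float = 0.5,
    mm_min: float = 0.8,
    top_n: int = 10,
) -> pd.DataFrame:
    """Screen hub genes from the key-module table.

    Keeps genes with ``GS > gs_min``, ``|MM| > mm_min`` and membership in
    ``de_genes``; sorts by K.in descending (ties by GS descending, then gene
    id) and returns the top ``top_n``. Candidate counts at each stage are
    logged and attached to ``df.attrs``.
    """
    de_genes = set(de_genes)
    gs_mm = table[(table["GS"] > gs_min) & (table["MM"].abs() > mm_min)]
    candidates = gs_mm[gs_mm.index.isin(de_genes)]
    logger.info(
        "hub screen: %d genes pass GS>%g & |MM|>%g; %d also differentially expressed",
        len(gs_mm), gs_min, mm_min, len(candidates),
    )
    ranked = candidates.sort_values(
        by=["K.in", "GS"], ascending=[False, False], kind="stable"
    )
    # deterministic final tie-break on gene id
    ranked = ranked.iloc[
        np.lexsort((ranked.index.to_numpy(), -ranked["GS"], -ranked["K.in"]))
    ]
    if len(ranked) < top_n:
        logger.warning("only %d hub candidates survive (requested %d)", len(ranked), top_n)
    hubs = ranked.head(top_n).copy()
    hubs.attrs["n_gs_mm"] = len(gs_mm)
    hubs.attrs["n_candidates"] = len(candidates)
    return hubs
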