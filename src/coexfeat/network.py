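"""Weighted gene co-expression network construction and module detection.

The pipeline follows the standard weighted-network recipe: gene-gene Pearson
correlations are raised to a soft-threshold power beta chosen so the network's
connectivity distribution is approximately scale-free (log-log linearity of
the degree density, fit R^2 above a bound, default 0.85); adjacency
``a_ij = |cor_ij|^beta`` is converted to the topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_{u != i,j} a_iu * a_uj,

whose complement ``1 - TOM`` is the clustering dissimilarity. Genes are
clustered by average-linkage hierarchical clustering; modules are the
maximal dendrogram branches that are clearly separated from the rest of the
tree (see :func:`detect_modules`), branches below the minimum size or
without separation are unassigned ("grey"), and modules are named by
descending size following the conventional colour order. Module eigengenes
(first principal component of the standardized module submatrix) summarise
each module per sample; modules whose eigengenes correlate above a merge
threshold are combined, and each eigengene's Pearson correlation with the
binary phenotype ranks the modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "Network",
    "adjacency_matrix",
    "scale_free_fit",
    "scan_soft_thresholds",
    "select_power",
    "compute_tom",
    "build_network",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "select_key_module",
    "MODULE_COLORS",
]

logger = logging.getLogger(__name__)

# Colour order used to name modules by descending size (largest = turquoise).
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

GREY = "grey"


@dataclass
class Network:
    """A built co-expression network at a fixed soft-threshold power."""

    power: float
    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    dissimilarity: pd.DataFrame
    connectivity: pd.Series


def _abs_correlation(matrix: ExpressionMatrix) -> np.ndarray:
    x = matrix.values.to_numpy(dtype=float)
    cor = np.corrcoef(x)
    np.fill_diagonal(cor, 1.0)
    return cor


def adjacency_matrix(correlation: np.ndarray, power: float, signed: bool = False) -> np.ndarray:
    """Unsigned (default) adjacency |cor|^beta; signed uses ((1+cor)/2)^beta."""
    if signed:
        return ((1.0 + correlation) / 2.0) ** power
    return np.abs(correlation) ** power


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float, float]:
    """Scale-free topology fit of a connectivity vector.

    The connectivity values are binned into ``n_bins`` equal-width bins (the
    conventional discretisation for this diagnostic); the empirical frequency
    p(k) of each non-empty bin is regressed against the bin-mean connectivity
    on log10-log10 axes. Returns ``(r_squared, slope, truncated_r_squared)``
    where the truncated model adds a linear ``k`` term to the regression.
    Fewer than 3 usable bins yields NaNs.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins or k.min() == k.max():
        return (np.nan, np.nan, np.nan)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=k, minlength=n_bins)
    ok = counts > 0
    if ok.sum() < 3:
        return (np.nan, np.nan, np.nan)
    mean_k = sums[ok] / counts[ok]
    density = counts[ok] / len(k)
    usable = (density > 0) & (mean_k > 0)
    if usable.sum() < 3:
        return (np.nan, np.nan, np.nan)
    log_k = np.log10(mean_k[usable])
    log_p = np.log10(density[usable])
    res = stats.linregress(log_k, log_p)
    r2 = float(res.rvalue**2)
    slope = float(res.slope)
    # truncated model: log p ~ log k + k
    design = np.column_stack([np.ones_like(log_k), log_k, mean_k[usable]])
    coef, *_ = np.linalg.lstsq(design, log_p, rcond=None)
    fitted = design @ coef
    ss_res = float(((log_p - fitted) ** 2).sum())
    ss_tot = float(((log_p - log_p.mean()) ** 2).sum())
    trunc_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return (r2, slope, trunc_r2)


def scan_soft_thresholds(
    matrix: ExpressionMatrix,
    powers=tuple(range(1, 21)),
    n_bins: int = 10,
    signed: bool = False,
) -> pd.DataFrame:
    """Grid-search candidate soft-threshold powers.

    Returns one row per power with columns ``Power, SFT.R.sq, slope,
    truncated.R.sq, mean.k, median.k, max.k``.
    """
    if matrix.n_genes < 3 or matrix.n_samples < 4:
        raise ValidationError("soft-threshold scan needs >= 3 genes and >= 4 samples")
    cor = _abs_correlation(matrix)
    rows = []
    for p in powers:
        a = adjacency_matrix(cor, p, signed=signed)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope, trunc = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "Power": p,
                "SFT.R.sq": r2,
                "slope": slope,
                "truncated.R.sq": trunc,
                "mean.k": float(k.mean()),
                "median.k": float(np.median(k)),
                "max.k": float(k.max()),
            }
        )
    return pd.DataFrame(rows)


def select_power(scan: pd.DataFrame, r2_min: float = 0.85) -> float:
    """Smallest power whose fit exceeds ``r2_min`` with a negative slope.

    Falls back to the power maximising the fit index (with a warning) when no
    candidate qualifies.
    """
    if scan.empty:
        raise ValidationError("empty soft-threshold scan")
    ok = scan[(scan["SFT.R.sq"] > r2_min) & (scan["slope"] < 0)]
    if len(ok):
        return float(ok.iloc[0]["Power"])
    best = scan.loc[scan["SFT.R.sq"].idxmax()]
    logger.warning(
        "no power reaches scale-free fit R^2 > %.2f; falling back to power %g "
        "(R^2 = %.3f)", r2_min, best["Power"], best["SFT.R.sq"],
    )
    return float(best["Power"])


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with unit diagonal."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    l = a0 @ a0  # l_ij = sum_u a_iu a_uj, u != i,j since diag(a0)=0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(
    matrix: ExpressionMatrix, power: float, signed: bool = False
) -> Network:
    """Correlation -> adjacency -> TOM -> dissimilarity at a fixed power."""
    genes = matrix.gene_ids
    cor = _abs_correlation(matrix)
    a = adjacency_matrix(cor, power, signed=signed)
    np.fill_diagonal(a, 1.0)
    tom = compute_tom(a)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    as_df = lambda m: pd.DataFrame(m, index=genes, columns=genes)
    return Network(
        power=power,
        correlation=as_df(cor),
        adjacency=as_df(a),
        tom=as_df(tom),
        dissimilarity=as_df(dissim),
        connectivity=pd.Series(k, index=genes, name="k"),
    )


def detect_modules(
    dissimilarity: pd.DataFrame | np.ndarray,
    min_size: int = 30,
    min_gap: float = 0.002,
    gene_ids=None,
) -> pd.Series:
    """Average-linkage clustering with a branch-separation tree cut.

    A module is a *maximal* subtree of the dendrogram that (a) contains at
    least ``min_size`` genes and (b) is separated from the rest of the tree:
    the merge that absorbs the subtree happens at least ``min_gap`` times
    the dendrogram's height range above the subtree's own topmost internal
    merge. Genuine co-expression branches complete well below the height at
    which they join anything else, while sub-branches of an unstructured
    background are absorbed almost immediately — so a large but incoherent
    background never qualifies as a module, at any network density. Genes
    outside any qualifying subtree are assigned to "grey"; modules are named
    by descending size following the conventional colour order. Fully
    deterministic.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        gene_ids = dissimilarity.index
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        if gene_ids is None:
            gene_ids = pd.RangeIndex(d.shape[0])
    n = d.shape[0]
    if d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity must be square")
    if not (0 < min_gap < 1):
        raise ValidationError("min_gap must be in (0, 1)")
    if min_size >= n:
        logger.warning("min_size %d >= n_genes %d: all genes grey", min_size, n)
        return pd.Series(GREY, index=gene_ids, name="module")

    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    # node i of the linkage creates cluster n+i at height z[i, 2]
    sizes = np.concatenate([np.ones(n, dtype=int), z[:, 3].astype(int)])
    heights = np.concatenate([np.zeros(n), z[:, 2]])
    parent_h = np.full(2 * n - 1, np.nan)
    for i in range(n - 1):
        parent_h[int(z[i, 0])] = z[i, 2]
        parent_h[int(z[i, 1])] = z[i, 2]
    span = z[:, 2].max() - z[:, 2].min()
    if span <= 0:
        logger.warning("degenerate dendrogram (all merges equal): all genes grey")
        return pd.Series(GREY, index=gene_ids, name="module")
    separation = parent_h - heights  # NaN at the root: never qualifies
    with np.errstate(invalid="ignore"):
        qualified = (sizes >= min_size) & (separation >= min_gap * span)

    # maximal qualified subtrees: descend from the root, stop at the first
    # qualified node on each path and collect its leaves
    children = {n + i: (int(z[i, 0]), int(z[i, 1])) for i in range(n - 1)}
    module_roots: list[int] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if qualified[node]:
            module_roots.append(node)
        elif node >= n:
            stack.extend(children[node])

    def leaves(root: int) -> list[int]:
        out, st = [], [root]
        while st:
            v = st.pop()
            if v < n:
                out.append(v)
            else:
                st.extend(children[v])
        return out

    members = {r: sorted(leaves(r)) for r in module_roots}
    ordered = sorted(module_roots, key=lambda r: (-sizes[r], members[r][0]))
    labels = pd.Series(GREY, index=gene_ids, name="module")
    for rank, r in enumerate(ordered):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.iloc[members[r]] = color
    logger.info(
        "detected %d modules (min size %d, min gap %.3f); %d genes grey",
        len(ordered), min_size, min_gap, int((labels == GREY).sum()),
    )
    return labels


def module_eigengenes(
    matrix: ExpressionMatrix, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First-PC summary profile (eigengene) per non-grey module.

    Each module's gene-standardized submatrix is decomposed by SVD; the
    eigengene is the leading right-singular vector (unit-norm sample scores),
    sign-oriented so it correlates non-negatively with the module's average
    standardized expression. Returns (ME matrix: modules x samples, explained
    variance per module).
    """
    labels = labels.reindex(matrix.gene_ids)
    me_rows, ev = {}, {}
    for mod in [m for m in labels.unique() if m != GREY]:
        genes = labels.index[labels == mod]
        if len(genes) < 2:
            raise ValidationError(f"module {mod!r} has fewer than 2 genes")
        sub = matrix.values.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).all():
            raise ValidationError(f"module {mod!r} is degenerate (zero variance)")
        sub = sub[sd > 0]
        sub = (sub - sub.mean(axis=1, keepdims=True)) / sd[sd > 0][:, None]
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        score = vt[0]
        avg = sub.mean(axis=0)
        if np.corrcoef(score, avg)[0, 1] < 0:
            score = -score
        me_rows[f"ME{mod}"] = score
        ev[f"ME{mod}"] = float(s[0] ** 2 / (s**2).sum())
    me = pd.DataFrame(me_rows, index=matrix.sample_ids).T
    return me, pd.Series(ev, name="explained_variance")


def merge_modules(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    threshold: float = 0.8,
) -> pd.Series:
    """Merge modules whose eigengenes correlate above ``threshold``.

    Iteratively merges the most-correlated eigengene pair (the smaller module
    adopts the larger module's label) and recomputes eigengenes; terminates
    when every pairwise eigengene correlation is <= threshold.
    """
    labels = labels.reindex(matrix.gene_ids).copy()
    while True:
        mods = [m for m in labels.unique() if m != GREY]
        if len(mods) < 2:
            return labels
        me, _ = module_eigengenes(matrix, labels)
        cor = np.corrcoef(me.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= threshold:
            return labels
        a = me.index[i][2:]  # strip "ME"
        b = me.index[j][2:]
        size_a = int((labels == a).sum())
        size_b = int((labels == b).sum())
        if size_a > size_b or (size_a == size_b and a < b):
            keep, drop = a, b
        else:
            keep, drop = b, a
        logger.info(
            "merging module %s into %s (eigengene cor %.3f)", drop, keep, cor[i, j]
        )
        labels[labels == drop] = keep


def module_trait_correlation(me: pd.DataFrame, phenotype: pd.Series) -> pd.DataFrame:
    """Pearson correlation (and t-test p) of each eigengene with the 0/1 trait."""
    y = np.asarray(phenotype, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("phenotype must contain both classes")
    n = len(y)
    rows = {}
    for mod, row in me.iterrows():
        v = row.to_numpy(dtype=float)
        if v.std() == 0:
            raise ValidationError(f"eigengene {mod!r} is constant")
        r = float(np.corrcoef(v, y)[0, 1])
        r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r_c * np.sqrt(n - 2) / np.sqrt(1 - r_c**2)
        p = float(2 * stats.t.sf(abs(t), n - 2))
        rows[mod] = {"PCC": r, "p.value": p}
    return pd.DataFrame(rows).T


def select_key_module(
    trait_cor: pd.DataFrame, sizes: pd.Series | None = None
) -> str:
    """Module with the largest |PCC| with the trait.

    Ties broken by smaller p-value, then larger module size, then name. The
    returned label has any leading "ME" stripped.
    """
    if trait_cor.empty:
        raise ValidationError("no modules to select from")
    df = trait_cor.copy()
    df["absPCC"] = df["PCC"].abs()
    df["size"] = 0
    if sizes is not None:
        for mod in df.index:
            name = mod[2:] if mod.startswith("ME") else mod
            df.loc[mod, "size"] = int(sizes.get(name, 0))
    df = df.sort_values(
        by=["absPCC", "p.value", "size"], ascending=[False, True, False], kind="stable"
    )
    best = df.index[0]
    return best[2:] if best.startswith("ME") else best
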