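"""Dataset merging, scaling, empirical-Bayes batch correction and PCA QC.

Merging follows the common microarray convention: duplicate probes mapping to
one gene symbol are collapsed to their per-sample median, datasets are joined
on the intersection of gene symbols, and linear-scale datasets are moved to
log2. Batch effects are modelled per gene as an additive location term plus a
multiplicative residual-scale term per batch,

    x_ij = x'_ij + gamma_ig + s_ig * eps_ij,

and removed by the parametric empirical-Bayes (ComBat-style) adjustment:
after gene-wise standardization, per-batch locations and scales are estimated
from phenotype-adjusted residuals, shrunk toward across-gene priors (normal
for locations, inverse-gamma for scales), subtracted/divided out, and the
data are returned to the original per-gene scale. The biological contrast is
protected by including the phenotype in the estimation design.

:class:`BatchCorrector` exposes a fit/transform split so a held-out batch can
be corrected without its samples influencing anything estimated from the
training batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "merge_datasets",
    "log2_if_needed",
    "standardize",
    "correct_batch",
    "BatchCorrector",
    "pca_qc",
    "batch_f_test",
]

logger = logging.getLogger(__name__)

# A dataset whose maximum exceeds this is taken to be on linear scale and is
# log2(x+1)-transformed; log2 microarray intensities rarely exceed ~20.
LINEAR_SCALE_MAX = 50.0


def merge_datasets(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge datasets on shared gene symbols.

    Within each dataset, rows sharing a gene symbol are collapsed to their
    per-sample median; the merged matrix keeps only genes present in every
    dataset, and concatenates all samples with their batch/phenotype labels.
    """
    if not matrices:
        raise ValidationError("merge_datasets requires at least one dataset")
    collapsed = []
    for m in matrices:
        v = m.values
        if v.index.duplicated().any():
            v = v.groupby(level=0, sort=False).median()
        collapsed.append(ExpressionMatrix(v, m.batch, m.phenotype))

    shared = collapsed[0].values.index
    for m in collapsed[1:]:
        shared = shared.intersection(m.values.index)
    if len(shared) == 0:
        raise ValidationError("no genes shared by all datasets (empty intersection)")
    shared = sorted(shared)

    all_samples = pd.Index([])
    for m in collapsed:
        all_samples = all_samples.append(m.values.columns)
    if all_samples.duplicated().any():
        dups = sorted(set(all_samples[all_samples.duplicated()]))
        raise ValidationError(f"duplicate sample ids across datasets: {dups[:10]}")

    values = pd.concat([m.values.loc[shared] for m in collapsed], axis=1)
    batch = pd.concat([m.batch for m in collapsed])
    phenotype = pd.concat([m.phenotype for m in collapsed])
    logger.info(
        "merged %d datasets: %d shared genes, %d samples",
        len(matrices), len(shared), values.shape[1],
    )
    return ExpressionMatrix(values, batch, phenotype)


def log2_if_needed(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x+1)-transform batches detected as linear scale; log batches pass.

    The decision is made per batch (each batch is one source dataset) using a
    max-value heuristic, and recorded in the log.
    """
    values = matrix.values.copy()
    for bid in matrix.batch.unique():
        cols = matrix.batch.index[matrix.batch == bid]
        block = values[cols]
        mx = float(block.to_numpy().max())
        if mx > LINEAR_SCALE_MAX:
            if (block.to_numpy() < 0).any():
                raise ValidationError(
                    f"batch {bid!r} detected as linear scale but has negative values"
                )
            values[cols] = np.log2(block + 1.0)
            logger.info("batch %s: max %.3g -> applied log2(x+1)", bid, mx)
        else:
            logger.info("batch %s: max %.3g -> already log scale", bid, mx)
    return matrix.with_values(values)


def standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, sample sd (n-1 denominator) 1.

    Constant genes are dropped with a warning; an all-constant matrix is an
    error.
    """
    x = matrix.values
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("all genes are constant; nothing to standardize")
    if not keep.all():
        logger.warning("dropping %d constant genes before standardization", int((~keep).sum()))
    x = x.loc[keep]
    out = x.sub(x.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return matrix.with_values(out)


def _trait_design(batch: pd.Series, phenotype: pd.Series) -> tuple[np.ndarray, list]:
    """Design matrix [batch one-hots | phenotype] (no intercept; full rank)."""
    batches = list(pd.unique(batch))
    d = np.zeros((len(batch), len(batches) + 1))
    for k, b in enumerate(batches):
        d[(batch == b).to_numpy(), k] = 1.0
    d[:, -1] = phenotype.to_numpy()
    return d, batches


@dataclass
class BatchCorrector:
    """Empirical-Bayes location/scale batch correction with a fit/transform API.

    ``fit_transform`` reproduces the usual all-batches-at-once correction.
    ``transform_new_batch`` corrects a batch unseen at fit time using the
    fitted per-gene standardization and phenotype effect, so nothing estimated
    from the training batches depends on held-out samples.
    """

    no_eb: bool = False
    mean_only: bool = False
    protect_phenotype: bool = True
    max_iter: int = 100
    tol: float = 1e-6

    # fitted state
    genes_: pd.Index = field(default=None, repr=False)
    grand_mean_: np.ndarray = field(default=None, repr=False)
    var_pooled_: np.ndarray = field(default=None, repr=False)
    pheno_effect_: np.ndarray = field(default=None, repr=False)

    # -- estimation helpers ----------------------------------------------------

    def _check(self, matrix: ExpressionMatrix, min_batches: int) -> None:
        counts = matrix.batch.value_counts()
        if len(counts) < min_batches:
            raise ValidationError(
                f"batch correction requires >= {min_batches} batches, got {len(counts)}"
            )
        small = counts[counts < 2]
        if len(small):
            raise ValidationError(
                f"batch(es) with fewer than 2 samples: {list(small.index)}"
            )

    def _drop_degenerate(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        x = matrix.values.to_numpy()
        keep = np.ones(matrix.n_genes, dtype=bool)
        for b in matrix.batch.unique():
            cols = (matrix.batch == b).to_numpy()
            keep &= x[:, cols].std(axis=1, ddof=1) > 0
        keep &= x.std(axis=1, ddof=1) > 0
        if not keep.all():
            logger.warning(
                "dropping %d genes with zero variance in some batch", int((~keep).sum())
            )
        if not keep.any():
            raise ValidationError("no gene has positive variance in every batch")
        return ExpressionMatrix(matrix.values.loc[keep], matrix.batch, matrix.phenotype)

    def _shrink(self, gamma_hat, delta_hat, resid, cols):
        """Posterior location/scale for one batch (parametric EB, iterative)."""
        n = int(cols.sum())
        if self.no_eb:
            return gamma_hat, (np.ones_like(delta_hat) if self.mean_only else delta_hat)
        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        a = (2 * s2 + m**2) / s2
        b = (m * s2 + m**3) / s2
        g_star = gamma_hat.copy()
        d_star = delta_hat.copy()
        r = resid[:, cols]
        for _ in range(self.max_iter):
            g_new = (n * t2 * gamma_hat + d_star * gamma_bar) / (n * t2 + d_star)
            sum2 = ((r - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
            change = max(
                np.abs(g_new - g_star).max(), np.abs(d_new - d_star).max()
            )
            g_star, d_star = g_new, d_new
            if change < self.tol:
                break
        if self.mean_only:
            d_star = np.ones_like(d_star)
        return g_star, d_star

    # -- public API ------------------------------------------------------------

    def fit_transform(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        """Estimate standardization + batch parameters and correct in place.

        Standardization divides by the pooled *residual* standard deviation
        (variance left after removing batch and phenotype effects), so the
        per-batch scale estimates measure noise scale only and the scale
        adjustment cannot inflate the biological contrast's residuals.
        """
        self._check(matrix, min_batches=2)
        matrix = self._drop_degenerate(matrix)
        x = matrix.values.to_numpy(dtype=float)
        n = x.shape[1]
        self.genes_ = matrix.values.index
        y = matrix.phenotype.to_numpy(dtype=float)

        design, batches = _trait_design(matrix.batch, matrix.phenotype)
        if not self.protect_phenotype:
            design = design[:, :-1]
        coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)  # (p, genes)
        batch_sizes = np.array([(matrix.batch == b).sum() for b in batches])
        batch_coef = coef[: len(batches)]  # per-batch per-gene locations
        self.grand_mean_ = (batch_sizes / n) @ batch_coef
        if self.protect_phenotype:
            self.pheno_effect_ = coef[-1]
        else:
            self.pheno_effect_ = np.zeros(len(self.genes_))
        fitted = (design @ coef).T
        self.var_pooled_ = ((x - fitted) ** 2).mean(axis=1)
        if (self.var_pooled_ <= 0).any():
            raise ValidationError("zero pooled residual variance for some gene")

        stand_mean = self.grand_mean_[:, None] + np.outer(self.pheno_effect_, y)
        root_vp = np.sqrt(self.var_pooled_)[:, None]
        s = (x - stand_mean) / root_vp  # batch effects + unit-scale residuals

        corrected = np.empty_like(s)
        batch_arr = matrix.batch.to_numpy()
        for b in batches:
            cols = batch_arr == b
            gamma_hat = s[:, cols].mean(axis=1)
            centred = s[:, cols] - gamma_hat[:, None]
            delta_hat = (centred**2).sum(axis=1) / (cols.sum() - 1)
            g_star, d_star = self._shrink(gamma_hat, delta_hat, s, cols)
            corrected[:, cols] = (s[:, cols] - g_star[:, None]) / np.sqrt(d_star)[:, None]
        out = corrected * root_vp + stand_mean
        return ExpressionMatrix(
            pd.DataFrame(out, index=self.genes_, columns=matrix.sample_ids),
            matrix.batch,
            matrix.phenotype,
        )

    def transform_new_batch(
        self, matrix: ExpressionMatrix, use_phenotype: bool = True
    ) -> ExpressionMatrix:
        """Correct a batch unseen at fit time.

        Standardization and the phenotype effect come from the fitted state;
        the new batch's own location/scale are estimated from its samples
        (shrinkage priors taken across genes within the batch). When
        ``use_phenotype`` the fitted — not re-estimated — phenotype effect is
        removed before estimating the location, so batch location estimates do
        not absorb the biological contrast.
        """
        if self.genes_ is None:
            raise ValidationError("corrector not fitted")
        self._check(matrix, min_batches=1)
        matrix = matrix.subset_genes(self.genes_)
        x = matrix.values.to_numpy(dtype=float)
        y = matrix.phenotype.to_numpy(dtype=float)
        if use_phenotype and self.protect_phenotype:
            pheno_part = np.outer(self.pheno_effect_, y)
        else:
            pheno_part = 0.0
        stand_mean = self.grand_mean_[:, None] + pheno_part
        root_vp = np.sqrt(self.var_pooled_)[:, None]
        s = (x - stand_mean) / root_vp

        corrected = np.empty_like(s)
        batch_arr = matrix.batch.to_numpy()
        for b in pd.unique(matrix.batch):
            cols = batch_arr == b
            gamma_hat = s[:, cols].mean(axis=1)
            centred = s[:, cols] - gamma_hat[:, None]
            delta_hat = (centred**2).sum(axis=1) / (cols.sum() - 1)
            delta_hat = np.maximum(delta_hat, 1e-12)
            g_star, d_star = self._shrink(gamma_hat, delta_hat, s, cols)
            corrected[:, cols] = (s[:, cols] - g_star[:, None]) / np.sqrt(d_star)[:, None]
        out = corrected * root_vp + stand_mean
        return ExpressionMatrix(
            pd.DataFrame(out, index=self.genes_, columns=matrix.sample_ids),
            matrix.batch,
            matrix.phenotype,
        )


def correct_batch(
    matrix: ExpressionMatrix,
    no_eb: bool = False,
    mean_only: bool = False,
    protect_phenotype: bool = True,
) -> ExpressionMatrix:
    """All-batches-at-once empirical-Bayes batch correction (functional API)."""
    return BatchCorrector(
        no_eb=no_eb, mean_only=mean_only, protect_phenotype=protect_phenotype
    ).fit_transform(matrix)


def pca_qc(matrix: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Per-sample scores on the top principal components, for batch QC.

    Returns a DataFrame indexed by sample id with columns ``PC1..PCk`` plus
    ``batch`` and ``phenotype``; explained-variance fractions are attached as
    ``df.attrs['explained_variance_ratio']``.
    """
    from sklearn.decomposition import PCA

    if n_components > min(matrix.n_genes, matrix.n_samples):
        raise ValidationError(
            f"n_components={n_components} exceeds min(genes, samples)="
            f"{min(matrix.n_genes, matrix.n_samples)}"
        )
    x = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if not np.isfinite(x).all():
        raise ValidationError("matrix contains non-finite values")
    if x.std() == 0:
        raise ValidationError("degenerate (constant) matrix")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0))
    df = pd.DataFrame(
        scores,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    df["batch"] = matrix.batch.values
    df["phenotype"] = matrix.phenotype.values
    df.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.copy()
    return df


def batch_f_test(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene one-way ANOVA p-value for a batch effect (vectorised)."""
    x = matrix.values.to_numpy(dtype=float)
    groups = [x[:, (matrix.batch == b).to_numpy()] for b in matrix.batch.unique()]
    k = len(groups)
    n = x.shape[1]
    grand = x.mean(axis=1)
    ss_between = sum(g.shape[1] * (g.mean(axis=1) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = stats.f.sf(f, k - 1, n - k)
    return pd.Series(p, index=matrix.gene_ids, name="batch_f_p")
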