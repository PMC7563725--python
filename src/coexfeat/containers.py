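"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`: a genes-by-samples matrix of
log2-scale expression values together with per-sample batch and phenotype
annotations. Values are held in a :class:`pandas.DataFrame` (gene symbols as
the row index, sample ids as columns) so that all alignment, subsetting and
I/O go through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample annotations.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index are gene symbols,
        columns are sample ids. Log2-scale expression.
    batch
        Per-sample batch label, indexed by sample id.
    phenotype
        Per-sample phenotype, 0 = normal, 1 = cancer, indexed by sample id.
    """

    values: pd.DataFrame
    batch: pd.Series
    phenotype: pd.Series

    def __post_init__(self) -> None:
        cols = self.values.columns
        self.batch = pd.Series(self.batch).reindex(cols)
        self.phenotype = pd.Series(self.phenotype).reindex(cols)
        if self.batch.isna().any():
            missing = list(cols[self.batch.isna()])
            raise ValidationError(f"samples missing batch labels: {missing}")
        if self.phenotype.isna().any():
            missing = list(cols[self.phenotype.isna()])
            raise ValidationError(f"samples missing phenotype labels: {missing}")
        bad = set(np.unique(self.phenotype.to_numpy())) - {0, 1}
        if bad:
            raise ValidationError(f"phenotype values outside {{0,1}}: {sorted(bad)}")
        self.phenotype = self.phenotype.astype(int)
        if self.values.columns.duplicated().any():
            dups = list(self.values.columns[self.values.columns.duplicated()])
            raise ValidationError(f"duplicate sample ids: {dups}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.batch, self.phenotype)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        """Restrict to the given samples, in the given order."""
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples], self.batch[samples], self.phenotype[samples]
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.batch.copy(), self.phenotype.copy())

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Return a matrix with the same annotations but new values."""
        return ExpressionMatrix(values, self.batch, self.phenotype)
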