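"""Feature fusion and SVM classification with a held-out-batch split.

The fused representation concatenates the expression of the screened hub
genes (one column per hub) with the VAE latent means (one column per latent
dimension) — 20 columns under the defaults (10 hubs + 10 latents). Features
are z-scaled with statistics computed on the training split only. The
classifier is a soft-margin SVM (linear kernel by default); AUC is computed
from decision-function scores by the Mann-Whitney rank formulation with tied
scores mid-ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

from .containers import ExpressionMatrix, ValidationError

__all__ = [
    "build_features",
    "split_by_batch",
    "train_svm",
    "evaluate",
    "auc_score",
    "ClassifierReport",
]

logger = logging.getLogger(__name__)


def build_features(
    matrix: ExpressionMatrix,
    hub_genes,
    latents: pd.DataFrame | None = None,
    train_samples=None,
) -> pd.DataFrame:
    """Samples x (hubs + latents) feature matrix, z-scaled by training stats.

    Parameters
    ----------
    hub_genes
        Gene ids whose expression rows become the first feature columns.
    latents
        Optional samples x latent_dim frame (aligned on sample id) appended
        after the hub columns; ``None`` gives a hubs-only matrix.
    train_samples
        Sample ids whose mean/sd define the scaling (default: all samples).
        The scaling statistics are attached as ``df.attrs``.
    """
    hub_genes = list(hub_genes)
    missing = [g for g in hub_genes if g not in matrix.gene_ids]
    if missing:
        raise ValidationError(f"hub gene(s) absent from matrix: {missing}")
    feats = matrix.values.loc[hub_genes].T.copy()
    if latents is not None:
        lat = latents.reindex(feats.index)
        if lat.isna().any().any():
            raise ValidationError("latent features missing for some samples")
        feats = pd.concat([feats, lat], axis=1)
    if feats.isna().any().any():
        raise ValidationError("feature matrix contains missing values")

    train_samples = list(train_samples) if train_samples is not None else list(feats.index)
    mean = feats.loc[train_samples].mean()
    sd = feats.loc[train_samples].std(ddof=1).replace(0.0, 1.0)
    scaled = (feats - mean) / sd
    scaled.attrs["scale_mean"] = mean
    scaled.attrs["scale_sd"] = sd
    return scaled


def split_by_batch(
    matrix: ExpressionMatrix, test_batch: str
) -> tuple[list[str], list[str]]:
    """All samples of ``test_batch`` form the test split; the rest train."""
    if test_batch not in set(matrix.batch):
        raise ValidationError(f"test batch {test_batch!r} not present")
    is_test = (matrix.batch == test_batch).to_numpy()
    train = list(matrix.sample_ids[~is_test])
    test = list(matrix.sample_ids[is_test])
    y = matrix.phenotype
    logger.info(
        "split: train %d (normal %d / cancer %d), test %d (normal %d / cancer %d)",
        len(train), int((y[train] == 0).sum()), int((y[train] == 1).sum()),
        len(test), int((y[test] == 0).sum()), int((y[test] == 1).sum()),
    )
    if len(set(y[test])) < 2:
        logger.warning("test split contains a single class; AUC will be undefined")
    return train, test


def train_svm(
    features: pd.DataFrame, labels: pd.Series, kernel: str = "linear", c: float = 1.0
) -> SVC:
    """Fit a soft-margin SVM; decision scores are exposed for AUC."""
    y = np.asarray(labels.reindex(features.index))
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    model = SVC(kernel=kernel, C=c)
    model.fit(features.to_numpy(dtype=float), y)
    return model


def auc_score(scores, labels) -> float | None:
    """ROC AUC by the Mann-Whitney rank statistic (ties mid-ranked).

    Returns ``None`` when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ClassifierReport:
    """Held-out evaluation summary."""

    accuracy: float
    auc: float | None
    confusion: list[list[int]]  # rows: true 0/1; cols: predicted 0/1
    scores: pd.Series
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion": self.confusion,
            "n_test": self.n_test,
        }


def evaluate(model: SVC, features: pd.DataFrame, labels: pd.Series) -> ClassifierReport:
    """Accuracy, rank-based AUC and confusion matrix on a test split."""
    if len(features) == 0:
        raise ValidationError("empty test set")
    y = np.asarray(labels.reindex(features.index))
    x = features.to_numpy(dtype=float)
    pred = model.predict(x)
    scores = model.decision_function(x)
    acc = float((pred == y).mean())
    auc = auc_score(scores, y)
    conf = [
        [int(((y == t) & (pred == p)).sum()) for p in (0, 1)] for t in (0, 1)
    ]
    return ClassifierReport(
        accuracy=acc,
        auc=auc,
        confusion=conf,
        scores=pd.Series(scores, index=features.index, name="decision_score"),
        n_test=len(y),
    )
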