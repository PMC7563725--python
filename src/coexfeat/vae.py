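"""Variational autoencoder for low-dimensional expression features (numpy).

A symmetric MLP: encoder ``input -> h1 -> h2 -> (mu, log sigma^2)``, decoder
``z -> h2 -> h1 -> input`` with ReLU hidden activations and a linear output
(inputs are per-gene standardized values, so a Gaussian likelihood / squared
reconstruction loss is the natural choice). Training minimises, per sample,

    sum over genes of the squared reconstruction error
    + kl_weight * KL( N(mu, sigma^2) || N(0, I) )   (summed over latent dims)

averaged over the batch; summing the reconstruction over genes keeps its
balance against the KL term independent of the input dimension. Optimisation
is Adam, sampling ``z = mu + sigma * eps`` during training (the
reparameterization trick). Inference (``encode``) returns the latent means —
deterministic classifier features. The default geometry is 584-100-10-100-584
around a 1159-gene input; hidden widths scale proportionally with other input
sizes. All forward/backward passes are explicit numpy, which keeps training
single-threaded-deterministic and makes the analytic gradients directly
checkable against finite differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ValidationError

__all__ = ["VAEConfig", "VAEModel", "train_vae", "encode", "reconstruction_error"]

logger = logging.getLogger(__name__)

REFERENCE_INPUT_DIM = 1159  # geometry anchor for the default hidden widths
REFERENCE_HIDDEN = (584, 100)


@dataclass
class VAEConfig:
    """Training configuration; defaults follow the reference geometry."""

    input_dim: int
    hidden_dims: tuple[int, int] | None = None  # None -> scaled from reference
    latent_dim: int = 10
    learning_rate: float = 0.0005
    batch_size: int = 20
    epochs: int = 6
    seed: int = 0
    kl_weight: float = 1.0

    def resolved_hidden(self) -> tuple[int, int]:
        if self.hidden_dims is not None:
            return self.hidden_dims
        if self.input_dim == REFERENCE_INPUT_DIM:
            return REFERENCE_HIDDEN
        ratio = self.input_dim / REFERENCE_INPUT_DIM
        h1 = max(self.latent_dim, int(round(REFERENCE_HIDDEN[0] * ratio)))
        h2 = max(self.latent_dim, int(round(REFERENCE_HIDDEN[1] * ratio)))
        return (h1, h2)

    def validate(self) -> None:
        if self.input_dim <= 0:
            raise ValidationError("input_dim must be positive")
        if self.latent_dim <= 0:
            raise ValidationError("latent_dim must be positive")
        if any(h <= 0 for h in self.resolved_hidden()):
            raise ValidationError("hidden dims must be positive")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.kl_weight < 0:
            raise ValidationError("kl_weight must be >= 0")


PARAM_NAMES = ["W1", "b1", "W2", "b2", "Wm", "bm", "Wv", "bv",
               "W3", "b3", "W4", "b4", "W5", "b5"]


def _init_params(config: VAEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    d = config.input_dim
    h1, h2 = config.resolved_hidden()
    l = config.latent_dim

    def he(n_in, n_out):
        return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

    def xavier(n_in, n_out):
        return rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out))

    return {
        "W1": he(d, h1), "b1": np.zeros(h1),
        "W2": he(h1, h2), "b2": np.zeros(h2),
        "Wm": xavier(h2, l), "bm": np.zeros(l),
        "Wv": xavier(h2, l), "bv": np.zeros(l),
        "W3": he(l, h2), "b3": np.zeros(h2),
        "W4": he(h2, h1), "b4": np.zeros(h1),
        "W5": xavier(h1, d), "b5": np.zeros(d),
    }


def _forward_backward(
    params: dict, x: np.ndarray, eps: np.ndarray, kl_weight: float
) -> tuple[float, float, dict]:
    """One batch: returns (recon_loss, kl_loss, gradients).

    ``x`` is (batch, genes); ``eps`` the reparameterization noise
    (batch, latent). Reconstruction loss is the mean squared error over all
    entries; KL is summed over latent dims and averaged over the batch.
    """
    b, _ = x.shape
    # encoder
    a1 = x @ params["W1"] + params["b1"]
    h1 = np.maximum(a1, 0.0)
    a2 = h1 @ params["W2"] + params["b2"]
    h2 = np.maximum(a2, 0.0)
    mu = h2 @ params["Wm"] + params["bm"]
    lv = h2 @ params["Wv"] + params["bv"]
    sigma = np.exp(0.5 * lv)
    z = mu + sigma * eps
    # decoder
    a3 = z @ params["W3"] + params["b3"]
    d1 = np.maximum(a3, 0.0)
    a4 = d1 @ params["W4"] + params["b4"]
    d2 = np.maximum(a4, 0.0)
    xhat = d2 @ params["W5"] + params["b5"]

    # per-sample squared reconstruction error summed over genes (Gaussian
    # likelihood scaling: keeps the balance against the latent-summed KL
    # independent of the input dimension), averaged over the batch
    recon = float(((xhat - x) ** 2).sum(axis=1).mean())
    kl = float((0.5 * (np.exp(lv) + mu**2 - 1.0 - lv)).sum(axis=1).mean())

    g = {}
    # decoder backward
    dxhat = 2.0 * (xhat - x) / b
    g["W5"] = d2.T @ dxhat
    g["b5"] = dxhat.sum(axis=0)
    dd2 = dxhat @ params["W5"].T
    da4 = dd2 * (a4 > 0)
    g["W4"] = d1.T @ da4
    g["b4"] = da4.sum(axis=0)
    dd1 = da4 @ params["W4"].T
    da3 = dd1 * (a3 > 0)
    g["W3"] = z.T @ da3
    g["b3"] = da3.sum(axis=0)
    dz = da3 @ params["W3"].T
    # reparameterization + KL
    dmu = dz + kl_weight * mu / b
    dlv = dz * (0.5 * sigma * eps) + kl_weight * 0.5 * (np.exp(lv) - 1.0) / b
    g["Wm"] = h2.T @ dmu
    g["bm"] = dmu.sum(axis=0)
    g["Wv"] = h2.T @ dlv
    g["bv"] = dlv.sum(axis=0)
    dh2 = dmu @ params["Wm"].T + dlv @ params["Wv"].T
    da2 = dh2 * (a2 > 0)
    g["W2"] = h1.T @ da2
    g["b2"] = da2.sum(axis=0)
    dh1 = da2 @ params["W2"].T
    da1 = dh1 * (a1 > 0)
    g["W1"] = x.T @ da1
    g["b1"] = da1.sum(axis=0)
    return recon, kl, g


@dataclass
class VAEModel:
    """Trained parameters plus the training history and input gene order."""

    config: VAEConfig
    params: dict[str, np.ndarray]
    gene_ids: list[str]
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def encode_array(self, x: np.ndarray) -> np.ndarray:
        """Latent means for (samples, genes) data; no sampling."""
        h1 = np.maximum(x @ self.params["W1"] + self.params["b1"], 0.0)
        h2 = np.maximum(h1 @ self.params["W2"] + self.params["b2"], 0.0)
        return h2 @ self.params["Wm"] + self.params["bm"]

    def decode_array(self, z: np.ndarray) -> np.ndarray:
        d1 = np.maximum(z @ self.params["W3"] + self.params["b3"], 0.0)
        d2 = np.maximum(d1 @ self.params["W4"] + self.params["b4"], 0.0)
        return d2 @ self.params["W5"] + self.params["b5"]

    def _check_genes(self, matrix: ExpressionMatrix) -> np.ndarray:
        given = list(matrix.gene_ids)
        if given != self.gene_ids:
            missing = sorted(set(self.gene_ids) - set(given))
            extra = sorted(set(given) - set(self.gene_ids))
            if missing or extra:
                raise ValidationError(
                    f"gene set mismatch: missing {missing[:5]}, extra {extra[:5]}"
                )
            # same set, different order: realign
            matrix = matrix.subset_genes(self.gene_ids)
        return matrix.values.to_numpy(dtype=float).T  # samples x genes


def train_vae(matrix: ExpressionMatrix, config: VAEConfig) -> VAEModel:
    """Train on (per-gene standardized) expression; samples are VAE rows.

    Batches are shuffled per epoch with the configured seed; identical
    config + data give bit-identical histories.
    """
    config.validate()
    x_all = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n, d = x_all.shape
    if d != config.input_dim:
        raise ValidationError(
            f"config.input_dim={config.input_dim} but matrix has {d} genes"
        )
    if n < config.batch_size:
        raise ValidationError(
            f"need >= batch_size={config.batch_size} samples, got {n}"
        )
    rng = np.random.default_rng(config.seed)
    params = _init_params(config, rng)
    m_adam = {k: np.zeros_like(v) for k, v in params.items()}
    v_adam = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        recon_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_all[idx]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            recon, kl, grads = _forward_backward(params, xb, eps, config.kl_weight)
            if not (np.isfinite(recon) and np.isfinite(kl)):
                raise ValidationError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            step += 1
            for k in params:
                m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * grads[k]
                v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * grads[k] ** 2
                m_hat = m_adam[k] / (1 - beta1**step)
                v_hat = v_adam[k] / (1 - beta2**step)
                params[k] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + adam_eps)
            recon_sum += recon
            kl_sum += kl
            n_batches += 1
        rows.append(
            {
                "epoch": epoch + 1,
                "recon_loss": recon_sum / n_batches,
                "kl_loss": kl_sum / n_batches,
                "total_loss": (recon_sum + config.kl_weight * kl_sum) / n_batches,
            }
        )
        logger.info(
            "epoch %d/%d: recon %.5f kl %.5f",
            epoch + 1, config.epochs, rows[-1]["recon_loss"], rows[-1]["kl_loss"],
        )
    return VAEModel(
        config=config,
        params=params,
        gene_ids=list(matrix.gene_ids),
        history=pd.DataFrame(rows),
    )


def encode(model: VAEModel, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Latent means (samples x latent_dim), aligned to the model's gene order."""
    x = model._check_genes(matrix)
    z = model.encode_array(x)
    return pd.DataFrame(
        z,
        index=matrix.sample_ids,
        columns=[f"latent{i + 1}" for i in range(z.shape[1])],
    )


def reconstruction_error(
    model: VAEModel, matrix: ExpressionMatrix
) -> tuple[pd.Series, float]:
    """MSE between input and its decoding from the latent means."""
    x = model._check_genes(matrix)
    xhat = model.decode_array(model.encode_array(x))
    per_sample = ((xhat - x) ** 2).mean(axis=1)
    return (
        pd.Series(per_sample, index=matrix.sample_ids, name="mse"),
        float(per_sample.mean()),
    )
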