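"""End-to-end orchestration: merge -> batch correction -> DE -> network ->
hub genes -> VAE -> fused features -> SVM, with a held-out-batch evaluation.

Two estimation policies are supported. The default ("strict") estimates
everything that feeds the classifier — standardization, batch priors, the DE
screen, the network and its modules, hub selection, VAE training and feature
scaling — from the training batches only; the held-out batch is corrected
with the fitted parameters plus its own location/scale and is never seen by
the model. ``paper_mode`` instead estimates the DE screen and the network on
all samples jointly (the common single-dataset workflow) while the classifier
is still trained on the training split only.

All thresholds live in :class:`PipelineConfig`; all randomness flows from one
root seed, split deterministically per stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, diffexpr, hubgenes, network, preprocess
from .containers import ExpressionMatrix, ValidationError
from .io import write_table
from .vae import VAEConfig, encode, train_vae

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with the standard defaults."""

    de_alpha: float = 0.05
    de_lfc: float = 1.0
    r2_min: float = 0.85
    min_module_size: int = 30
    merge_cor: float = 0.8
    gs_min: float = 0.5
    mm_min: float = 0.8
    top_n_hubs: int = 10
    powers: tuple = tuple(range(1, 21))
    sft_bins: int = 10
    signed_network: bool = False
    # VAE
    latent_dim: int = 10
    vae_hidden: tuple | None = None  # None -> scaled from the reference geometry
    vae_learning_rate: float = 0.0005
    vae_batch_size: int = 20
    vae_epochs: int = 6
    vae_kl_weight: float = 1.0
    # classifier
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    # control
    test_batch: str | None = None  # None -> last batch in order of appearance
    seed: int = 0
    paper_mode: bool = False

    def validate(self) -> None:
        for name in ("de_alpha", "de_lfc", "gs_min", "mm_min", "r2_min", "merge_cor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not (0 < self.de_alpha < 1):
            raise ValidationError("de_alpha must be in (0, 1)")
        if self.min_module_size < 2 or self.top_n_hubs < 1:
            raise ValidationError("min_module_size >= 2 and top_n_hubs >= 1 required")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["powers"] = list(self.powers)
        d["vae_hidden"] = list(self.vae_hidden) if self.vae_hidden else None
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "powers" in d and d["powers"] is not None:
            d["powers"] = tuple(d["powers"])
        if d.get("vae_hidden"):
            d["vae_hidden"] = tuple(d["vae_hidden"])
        return cls(**d)


def _stage_seeds(root: int, n: int = 4) -> list[int]:
    """Deterministic per-stage child seeds below 2**31."""
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(
    matrix: ExpressionMatrix,
    config: PipelineConfig | None = None,
    output_dir=None,
) -> dict:
    """Run the full feature-extraction + classification pipeline.

    Parameters
    ----------
    matrix
        Merged, log2-scale expression with batch and phenotype annotations.
    config
        Thresholds and stage settings; defaults are the standard values.
    output_dir
        When given, every stage artifact (tables, metrics JSON) is written
        beneath it.

    Returns
    -------
    dict with stage summaries: gene/sample counts, the selected power, module
    sizes, the key module, hub genes, VAE history, and the classifier report
    with hubs-only / latents-only ablations.
    """
    config = config or PipelineConfig()
    config.validate()
    out = Path(output_dir) if output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    vae_seed, _, _, _ = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed, "paper_mode": config.paper_mode}
    summary["thresholds"] = {
        "de_alpha": config.de_alpha,
        "de_lfc": config.de_lfc,
        "r2_min": config.r2_min,
        "min_module_size": config.min_module_size,
        "merge_cor": config.merge_cor,
        "gs_min": config.gs_min,
        "mm_min": config.mm_min,
        "top_n_hubs": config.top_n_hubs,
    }
    logger.info("thresholds: %s", summary["thresholds"])

    # ---- split ---------------------------------------------------------------
    test_batch = config.test_batch or list(pd.unique(matrix.batch))[-1]
    train_ids, test_ids = classify.split_by_batch(matrix, test_batch)
    y = matrix.phenotype
    summary["split"] = {
        "test_batch": test_batch,
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "train_classes": [int((y[train_ids] == 0).sum()), int((y[train_ids] == 1).sum())],
        "test_classes": [int((y[test_ids] == 0).sum()), int((y[test_ids] == 1).sum())],
    }

    # ---- scaling + batch correction -----------------------------------------
    matrix = preprocess.log2_if_needed(matrix)
    qc_pre = preprocess.pca_qc(matrix, n_components=2)
    corrector = preprocess.BatchCorrector()
    train_m = matrix.subset_samples(train_ids)
    test_m = matrix.subset_samples(test_ids)
    train_c = corrector.fit_transform(train_m)
    test_c = corrector.transform_new_batch(test_m.subset_genes(corrector.genes_))
    full_c = ExpressionMatrix(
        pd.concat([train_c.values, test_c.values], axis=1)[
            [s for s in matrix.sample_ids if s in train_ids + test_ids]
        ],
        matrix.batch,
        matrix.phenotype,
    )
    qc_post = preprocess.pca_qc(full_c, n_components=2)
    summary["n_genes"] = full_c.n_genes
    summary["n_samples"] = full_c.n_samples

    fit_m = full_c if config.paper_mode else full_c.subset_samples(train_ids)

    # ---- differential expression --------------------------------------------
    de = diffexpr.moderated_t_test(fit_m)
    de_hits = diffexpr.screen_de(de, alpha=config.de_alpha, lfc=config.de_lfc)
    summary["de"] = {
        "n_significant": len(de_hits),
        "n_up": de_hits.attrs["n_up"],
        "n_down": de_hits.attrs["n_down"],
    }

    # ---- co-expression network ----------------------------------------------
    scan = network.scan_soft_thresholds(
        fit_m, powers=config.powers, n_bins=config.sft_bins,
        signed=config.signed_network,
    )
    power = network.select_power(scan, r2_min=config.r2_min)
    net = network.build_network(fit_m, power, signed=config.signed_network)
    labels = network.detect_modules(net.dissimilarity, min_size=config.min_module_size)
    labels = network.merge_modules(fit_m, labels, threshold=config.merge_cor)
    me, explained = network.module_eigengenes(fit_m, labels)
    trait = network.module_trait_correlation(me, fit_m.phenotype)
    sizes = labels[labels != network.GREY].value_counts()
    key = network.select_key_module(trait, sizes=sizes)
    summary["network"] = {
        "power": power,
        "sft_r2_at_power": float(
            scan.loc[scan["Power"] == power, "SFT.R.sq"].iloc[0]
        ),
        "modules": sizes.to_dict(),
        "key_module": key,
    }
    logger.info("selected power %g; key module %s", power, key)

    # ---- hub genes -----------------------------------------------------------
    hub_table = hubgenes.build_hub_table(fit_m, net.adjacency, me, labels, de)
    key_table = hub_table[hub_table["module"] == key]
    hubs = hubgenes.screen_hubs(
        key_table,
        de_hits.index,
        gs_min=config.gs_min,
        mm_min=config.mm_min,
        top_n=config.top_n_hubs,
    )
    summary["hubs"] = {
        "genes": list(hubs.index),
        "n_gs_mm": hubs.attrs["n_gs_mm"],
        "n_candidates": hubs.attrs["n_candidates"],
    }

    # ---- VAE latent features -------------------------------------------------
    de_genes = list(de_hits.index)
    sub_train = full_c.subset_samples(train_ids).subset_genes(de_genes)
    mu_g = sub_train.values.mean(axis=1)
    sd_g = sub_train.values.std(axis=1, ddof=1).replace(0.0, 1.0)
    std_all = full_c.subset_genes(de_genes).values.sub(mu_g, axis=0).div(sd_g, axis=0)
    std_train = ExpressionMatrix(std_all[train_ids], matrix.batch, matrix.phenotype)
    vae_cfg = VAEConfig(
        input_dim=len(de_genes),
        hidden_dims=config.vae_hidden,
        latent_dim=config.latent_dim,
        learning_rate=config.vae_learning_rate,
        batch_size=config.vae_batch_size,
        epochs=config.vae_epochs,
        seed=vae_seed,
        kl_weight=config.vae_kl_weight,
    )
    model = train_vae(std_train, vae_cfg)
    std_full = ExpressionMatrix(std_all, matrix.batch, matrix.phenotype)
    latents = encode(model, std_full)
    summary["vae"] = {
        "input_dim": vae_cfg.input_dim,
        "hidden": list(vae_cfg.resolved_hidden()),
        "history": model.history.to_dict(orient="list"),
    }

    # ---- fused classifier ----------------------------------------------------
    def _fit_eval(feats: pd.DataFrame) -> dict:
        svm = classify.train_svm(
            feats.loc[train_ids], y, kernel=config.svm_kernel, c=config.svm_c
        )
        report = classify.evaluate(svm, feats.loc[test_ids], y)
        return report.to_dict()

    fused = classify.build_features(
        full_c, list(hubs.index), latents, train_samples=train_ids
    )
    hub_only = classify.build_features(
        full_c, list(hubs.index), None, train_samples=train_ids
    )
    lat_only = latents.copy()
    lat_mu = lat_only.loc[train_ids].mean()
    lat_sd = lat_only.loc[train_ids].std(ddof=1).replace(0.0, 1.0)
    lat_only = (lat_only - lat_mu) / lat_sd

    summary["classifier"] = _fit_eval(fused)
    summary["ablations"] = {
        "hubs_only": _fit_eval(hub_only),
        "latents_only": _fit_eval(lat_only),
    }
    summary["runtime_s"] = round(time.time() - t0, 2)

    # ---- artifacts -----------------------------------------------------------
    if out:
        write_table(qc_pre, out / "pca_qc_pre.tsv", index_label="sample")
        write_table(qc_post, out / "pca_qc_post.tsv", index_label="sample")
        write_table(scan, out / "soft_threshold_scan.tsv")
        write_table(de, out / "de_table.tsv", index_label="gene")
        write_table(de_hits, out / "de_significant.tsv", index_label="gene")
        write_table(labels.to_frame(), out / "modules.tsv", index_label="gene")
        write_table(me, out / "module_eigengenes.tsv", index_label="module")
        write_table(trait, out / "module_trait.tsv", index_label="module")
        hub_out = hubs.rename(columns={"MM": f"MM.{key}"})
        write_table(hub_out, out / "hub_genes.tsv", index_label="GENE NAME")
        write_table(latents, out / "vae_latents.tsv", index_label="sample")
        write_table(fused, out / "features.tsv", index_label="sample")
        (out / "metrics.json").write_text(
            json.dumps(
                {
                    "accuracy": summary["classifier"]["accuracy"],
                    "auc": summary["classifier"]["auc"],
                    "confusion": summary["classifier"]["confusion"],
                    "split": summary["split"],
                    "ablations": summary["ablations"],
                    "de": summary["de"],
                    "network": summary["network"],
                    "hubs": summary["hubs"]["genes"],
                    "seed": config.seed,
                },
                indent=2,
            )
        )
    return summary
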