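"""End-to-end pipeline: phantom generation, training, database construction
and leave-query-out retrieval evaluation.

A single global seed fans out deterministically (via ``SeedSequence``) to the
phantom generator, the weight initialisation and the training loop, so the
whole run — including the metrics file — is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .feature_store import build_database, fit_pca
from .nn.network import NetworkConfig, build_network, extract_descriptors
from .phantoms import PhantomSpec, generate_phantom_set, write_image_set
from .retrieval import evaluate_database
from .training import TrainConfig, train, write_training_log

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Desk-scale defaults for the full study: 3 phantom classes of 50
    noise-free 48x48 images in two modality regimes, a 20-epoch training
    run, PCA reduction and top-10 retrieval evaluation."""

    image_size: int = 48
    n_classes: int = 3
    n_per_class: int = 50
    modality_mix: float = 0.5
    noise_sigma: float = 0.0
    module_channels: tuple[int, int, int] = (24, 48, 96)
    feature_dim: int = 4096
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    val_fraction: float = 0.2
    reduction_k: int = 1024
    use_pca: bool = True
    top_k: int = 10
    seed: int = 0
    save_images: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "module_channels" in raw:
            raw["module_channels"] = tuple(raw["module_channels"])
        return cls(**raw)

    def seeds(self) -> dict[str, int]:
        """Stage seeds derived from the global seed (kept below 2**31)."""
        state = np.random.SeedSequence(self.seed).generate_state(3) % (2**31)
        return {
            "phantom": int(state[0]),
            "init": int(state[1]),
            "train": int(state[2]),
        }


def _digest(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=list).encode()
    ).hexdigest()[:16]


def write_metrics_csv(df, map_value: float, path: str | Path) -> Path:
    """Per-query precision/recall/AP rows followed by a MAP summary line."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        df.to_csv(fh, index=False, float_format="%.8f")
        fh.write(f"MAP,,,,{map_value:.8f}\n")
    return path


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute generate -> train -> build-db -> evaluate.

    Writes ``metrics.csv``, ``training_log.csv``, ``model.npz``,
    ``features.h5`` and ``summary.json`` under ``out_dir`` and returns the
    summary dict.  Any stage failure raises :class:`PipelineError` naming
    the stage; outputs of completed stages are left in place.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = cfg.seeds()

    stage = "generate"
    try:
        spec = PhantomSpec(
            image_size=cfg.image_size,
            n_classes=cfg.n_classes,
            n_per_class=cfg.n_per_class,
            modality_mix=cfg.modality_mix,
            noise_sigma=cfg.noise_sigma,
            seed=seeds["phantom"],
        )
        images = generate_phantom_set(spec)
        if cfg.save_images:
            write_image_set(images, out_dir / "images")
        logger.info("generated %d phantom images", len(images))
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "train"
    try:
        net_cfg = NetworkConfig(
            input_size=cfg.image_size,
            module_channels=cfg.module_channels,
            feature_dim=cfg.feature_dim,
            n_classes=cfg.n_classes,
        )
        network = build_network(net_cfg, seed=seeds["init"])
        train_cfg = TrainConfig(
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            optimizer=cfg.optimizer,
            seed=seeds["train"],
            val_fraction=cfg.val_fraction,
        )
        report = train(network, images, train_cfg, out_dir / "model.npz")
        write_training_log(report, out_dir / "training_log.csv")
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "build-db"
    try:
        pca = None
        if cfg.use_pca:
            descriptors = extract_descriptors(network, images)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pca = fit_pca(descriptors, k=cfg.reduction_k)
        db = build_database(
            network,
            pca,
            images,
            out_dir / "features.h5",
            metadata={"config_digest": _digest(cfg)},
        )
        logger.info("feature database: %d records, dim %d", len(db), db.dim)
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "evaluate"
    try:
        per_query, map_value = evaluate_database(db, top_k=cfg.top_k)
        write_metrics_csv(per_query, map_value, out_dir / "metrics.csv")
    except Exception as e:
        raise PipelineError(stage, e) from e

    summary = {
        "config": asdict(cfg),
        "config_digest": _digest(cfg),
        "seeds": seeds,
        "n_images": len(images),
        "db_dim": int(db.dim),
        "db_digest": db.content_digest(),
        "final_val_accuracy": report.val_accuracy[-1] if report.val_accuracy else None,
        "map": map_value,
        "mean_precision": float(per_query["precision"].mean()),
        "mean_recall": float(per_query["recall"].mean()),
        "top_k": cfg.top_k,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=list)
    return summary
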