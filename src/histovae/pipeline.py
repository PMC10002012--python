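"""Experiment orchestration: baseline CNN vs reconstruct-then-classify arms.

Three experimental arms share one dataset split:

* ``baseline`` — train and evaluate the CNN on the original images;
* ``cvae``     — train the convolutional VAE (noise factor 0), reconstruct
  every partition, then train and evaluate the CNN on the reconstructions;
* ``dvae``     — the same with the denoising VAE (noise factor 0.2).

Each arm yields a full :class:`~histovae.metrics.MetricReport`; the three
reports form a comparison table with one metric per row.  Every source of
randomness (data generation, split, VAE init/sampling, CNN init/dropout) is
derived from a single master seed through independent child streams, so a
rerun with the same config reproduces the report bit-for-bit, and changing
one component's seed leaves the others' checkpoints untouched.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, metrics, preprocess, synthetic_data, vae_core

logger = logging.getLogger(__name__)

ARMS = ("baseline", "cvae", "dvae")
NOISE_FACTORS = {"baseline": 0.0, "cvae": 0.0, "dvae": 0.2}

# Partition fractions follow the 28k/10k/12k train/test/validation split
# ratio (0.56 / 0.20 / 0.24) used at full scale.
SPLIT_FRACTIONS = (0.56, 0.20, 0.24)

__all__ = [
    "ExperimentConfig",
    "ComparisonReport",
    "make_synthetic_bundle",
    "run_arm",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a three-arm comparison run.

    The desk-scale defaults (300 patches per class, 10 VAE + 5 CNN epochs)
    run the full three-arm experiment on one CPU in minutes; for real patch
    directories set ``data_dir`` and ``per_class`` instead.
    """

    arms: tuple = ARMS
    data_dir: str = None          # PNG class-directory root, or None for synthetic
    bundle_path: str = None       # pre-split array archive, overrides the above
    per_class: int = 300
    texture_params: synthetic_data.TextureParams = field(
        default_factory=synthetic_data.TextureParams
    )
    vae_epochs: int = 10
    cnn_epochs: int = 5
    batch_size: int = 64
    vae_learning_rate: float = 1e-3
    cnn_learning_rate: float = 5e-4
    noise_factor: float = 0.2     # for the dvae arm
    eval_on_reconstructed: bool = True
    stratify_split: bool = False
    seed: int = 0
    out_dir: str = None

    def __post_init__(self):
        if isinstance(self.arms, str):
            self.arms = (self.arms,)
        self.arms = tuple(self.arms)
        if not self.arms:
            raise ValueError("at least one experimental arm is required")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ValueError(f"unknown arm(s) {sorted(unknown)}; valid: {ARMS}")


@dataclass
class ComparisonReport:
    reports: dict                 # arm -> MetricReport
    config: ExperimentConfig
    seeds: dict

    def to_frame(self) -> pd.DataFrame:
        """Comparison table: one metric per row, one column per arm."""
        data = {arm: rep.as_rows() for arm, rep in self.reports.items()}
        return pd.DataFrame(data, index=list(metrics.REPORT_ROWS))

    def to_dict(self) -> dict:
        return {
            "reports": {arm: rep.to_dict() for arm, rep in self.reports.items()},
            "seeds": self.seeds,
        }


def _component_seeds(master_seed: int) -> dict:
    """Stable per-component seeds derived from the master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    names = ("data", "split", "vae_cvae", "vae_dvae", "cnn", "reconstruct")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def make_synthetic_bundle(n_per_class: int, seed: int,
                          params: synthetic_data.TextureParams = None,
                          stratify: bool = False) -> preprocess.DatasetBundle:
    """Generate a synthetic dataset and split it train/test/validation."""
    seeds = _component_seeds(seed)
    images, labels = synthetic_data.generate_dataset(
        n_per_class, params or synthetic_data.TextureParams(), seed=seeds["data"]
    )
    n = len(labels)
    n_train = int(round(SPLIT_FRACTIONS[0] * n))
    n_test = int(round(SPLIT_FRACTIONS[1] * n))
    sizes = (n_train, n_test, n - n_train - n_test)
    return preprocess.split_dataset(images, labels, sizes, seed=seeds["split"],
                                    stratify=stratify)


def _load_data(config: ExperimentConfig) -> preprocess.DatasetBundle:
    if config.bundle_path:
        return preprocess.load_bundle(config.bundle_path)
    seeds = _component_seeds(config.seed)
    if config.data_dir:
        patches = preprocess.load_patch_dir(config.data_dir)
        patches = preprocess.sample_balanced(patches, config.per_class, seeds["data"])
        images, labels = preprocess.preprocess_patches(patches)
        n = len(labels)
        n_train = int(round(SPLIT_FRACTIONS[0] * n))
        n_test = int(round(SPLIT_FRACTIONS[1] * n))
        sizes = (n_train, n_test, n - n_train - n_test)
        return preprocess.split_dataset(images, labels, sizes, seed=seeds["split"],
                                        stratify=config.stratify_split)
    return make_synthetic_bundle(config.per_class, config.seed,
                                 config.texture_params, config.stratify_split)


def run_arm(arm: str, data: preprocess.DatasetBundle, config: ExperimentConfig,
            out_dir: Path = None):
    """Run one experimental arm and return its MetricReport (plus artifacts).

    For VAE arms, the VAE is trained on the training partition, all three
    partitions are reconstructed, and the CNN is trained — and by default
    also evaluated — on the reconstructions.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; valid: {ARMS}")
    seeds = _component_seeds(config.seed)
    artifacts = {}

    if arm == "baseline":
        cnn_data = data
    else:
        vae_seed = seeds["vae_cvae"] if arm == "cvae" else seeds["vae_dvae"]
        vae_config = vae_core.VaeConfig(
            noise_factor=config.noise_factor if arm == "dvae" else 0.0,
            learning_rate=config.vae_learning_rate,
            epochs=config.vae_epochs,
            batch_size=config.batch_size,
            seed=vae_seed,
        )
        vae = vae_core.build_vae(vae_config)
        vae, vae_history = vae_core.train_vae(vae, data, vae_config)
        artifacts["vae"] = vae
        artifacts["vae_history"] = vae_history
        rec_seed = seeds["reconstruct"]
        cnn_data = preprocess.DatasetBundle(
            train_images=vae_core.reconstruct(vae, data.train_images, seed=rec_seed),
            train_labels=data.train_labels,
            val_images=vae_core.reconstruct(vae, data.val_images, seed=rec_seed + 1),
            val_labels=data.val_labels,
            test_images=vae_core.reconstruct(vae, data.test_images, seed=rec_seed + 2),
            test_labels=data.test_labels,
            meta=dict(data.meta, reconstructed_by=arm),
        )
        if out_dir is not None:
            vae_core.save_vae(vae, out_dir / f"vae_{arm}.npz")

    cnn_config = classifier.CnnConfig(
        learning_rate=config.cnn_learning_rate,
        epochs=config.cnn_epochs,
        batch_size=config.batch_size,
        seed=seeds["cnn"],
    )
    cnn = classifier.build_cnn(cnn_config)
    cnn, cnn_history = classifier.train_cnn(cnn, cnn_data, cnn_config)
    artifacts["cnn"] = cnn
    artifacts["cnn_history"] = cnn_history
    if out_dir is not None:
        classifier.save_cnn(cnn, out_dir / f"cnn_{arm}.npz")

    eval_images = (
        cnn_data.test_images if config.eval_on_reconstructed else data.test_images
    )
    scores, y_pred = classifier.predict(cnn, eval_images)
    y_true = data.test_labels
    loss = classifier.categorical_cross_entropy(
        scores, y_true, cnn_config.head_activation
    )
    report = metrics.evaluate(
        y_true, y_pred, classifier.positive_scores(cnn, scores), loss=loss
    )
    logger.info("arm %s: accuracy=%.4f kappa=%.4f auc=%.4f",
                arm, report.accuracy, report.kappa, report.roc_auc)
    return report, artifacts


def run_experiment(config: ExperimentConfig) -> ComparisonReport:
    """Run every requested arm on a shared split and assemble the report.

    When ``config.out_dir`` is set, writes ``report.csv`` / ``report.json``,
    model checkpoints, and an echo of the configuration; arm failures are
    recorded in the JSON report without discarding completed arms.
    """
    seeds = _component_seeds(config.seed)
    out_dir = None
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    data = _load_data(config)
    reports, failures = {}, {}
    for arm in config.arms:
        try:
            reports[arm], _ = run_arm(arm, data, config, out_dir)
        except Exception as exc:  # keep completed arms on a later failure
            logger.exception("arm %s failed", arm)
            failures[arm] = f"{type(exc).__name__}: {exc}"
    comparison = ComparisonReport(reports=reports, config=config, seeds=seeds)
    if out_dir is not None:
        comparison.to_frame().to_csv(out_dir / "report.csv")
        payload = comparison.to_dict()
        payload["failures"] = failures
        cfg = asdict(config)
        cfg["texture_params"] = asdict(config.texture_params)
        payload["config"] = cfg
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
    if failures and not reports:
        raise RuntimeError(f"every arm failed: {failures}")
    return comparison
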