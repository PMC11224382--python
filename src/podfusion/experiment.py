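"""End-to-end experiment driver: the three-way source comparison.

For each data source (rgb | hyperspectral | fusion) and each model (four
classical baselines + the residual network) the driver preprocesses, splits
70/30 stratified (test share rounded up, so 416 samples give 125 test),
fits, evaluates on the held-out split, and emits a summary table laid out as
metrics x source x model.  Optionally the spectral bands are first scored by
distance correlation on the training split and all unselected bands zeroed
(band ablation) before modelling.  Everything is seeded and re-runnable;
written artifacts carry a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import bands as band_mod
from . import baselines as base_mod
from . import evaluation as eval_mod
from . import resnet_rh as net_mod
from .errors import InvalidClassError, ManifestError
from .fusion import fuse_dataset, reshape_spectrum_2d, scale_spectral_plane
from .rgb import FUSION_SHAPE, crop_downsample
from .spectral import msc_correct
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset

logger = logging.getLogger("podfusion")

SOURCES = ("rgb", "hyperspectral", "fusion")
MODELS = base_mod.BASELINE_NAMES + ("resnet_rh",)


@dataclass
class ExperimentConfig:
    """Everything needed to re-run the three-way comparison."""

    generator: GeneratorConfig | None = None
    manifest: str | None = None
    seed: int = 0
    train_fraction: float = 0.70
    models: tuple[str, ...] = MODELS
    sources: tuple[str, ...] = SOURCES
    band_ablation: bool = False
    band_threshold: float = band_mod.DEFAULT_THRESHOLD
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    base_channels: int = 16
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.generator is None and self.manifest is None:
            self.generator = GeneratorConfig()
        if not self.models:
            raise ManifestError("experiment needs at least one model")
        for m in self.models:
            if m not in MODELS:
                raise ManifestError(f"unknown model {m!r}")
        for s in self.sources:
            if s not in SOURCES:
                raise ManifestError(f"unknown source {s!r}")

    def hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def read_manifest(path: str | Path) -> SyntheticDataset:
    """Load a paired dataset written by ``SyntheticDataset.save``.

    Validates that image count, spectrum count and label count agree, that
    every image file exists, and that labels lie in 0..3.
    """
    path = Path(path)
    manifest = json.loads(path.read_text())
    root = path.parent
    table = np.loadtxt(root / manifest["spectra_csv"], delimiter=",", skiprows=1)
    table = np.atleast_2d(table)
    spectra, csv_labels = table[:, :-1], table[:, -1].astype(int)
    wavelengths = np.array(
        [float(w) for w in (root / manifest["spectra_csv"]).read_text().splitlines()[0].split(",")[:-1]]
    )
    labels = np.asarray(manifest["labels"], dtype=int)
    if not (len(manifest["images"]) == spectra.shape[0] == labels.size):
        raise ManifestError(
            f"count mismatch: {len(manifest['images'])} images, "
            f"{spectra.shape[0]} spectra, {labels.size} labels"
        )
    if np.any(csv_labels != labels):
        raise ManifestError("labels in spectra CSV disagree with the manifest")
    if labels.size and (labels.min() < 0 or labels.max() > 3):
        raise InvalidClassError("manifest labels outside 0..3")
    images = []
    for i, rel in enumerate(manifest["images"]):
        img_path = root / rel
        if not img_path.exists():
            raise ManifestError(f"sample {i}: image file {rel} missing")
        images.append(np.asarray(Image.open(img_path), dtype=float) / 255.0)
    return SyntheticDataset(
        spectra=spectra,
        images=np.stack(images),
        labels=labels,
        wavelengths=wavelengths,
        truth=manifest.get("truth", {}),
    )


@dataclass
class ExperimentResult:
    reports: dict = field(default_factory=dict)
    confusions: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    band_mask: band_mod.BandMask | None = None
    split: tuple[np.ndarray, np.ndarray] | None = None
    config_hash: str = ""


def _representations(dataset: SyntheticDataset) -> dict:
    """Build the per-source model inputs from raw paired data."""
    rgb_small = np.stack([crop_downsample(img) for img in dataset.images])
    corrected, _ = msc_correct(dataset.spectra)
    planes = np.stack(
        [scale_spectral_plane(reshape_spectrum_2d(s, *FUSION_SHAPE)) for s in corrected]
    )
    fused = np.stack([s.tensor for s in fuse_dataset(rgb_small, corrected, dataset.labels)])
    return {
        "rgb_small": rgb_small,
        "corrected": corrected,
        "planes": planes,
        "fused": fused,
    }


def _source_tensors(rep: dict, source: str) -> np.ndarray:
    if source == "rgb":
        return rep["rgb_small"]
    if source == "hyperspectral":
        return rep["planes"][:, :, :, None]
    return rep["fused"]


def _source_features(rep: dict, source: str) -> np.ndarray:
    if source == "rgb":
        return rep["rgb_small"].reshape(len(rep["rgb_small"]), -1)
    if source == "hyperspectral":
        return rep["corrected"]
    return rep["fused"].reshape(len(rep["fused"]), -1)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Fit and evaluate every requested (source, model) pair; see module docs."""
    if config.manifest is not None:
        dataset = read_manifest(config.manifest)
    else:
        dataset = generate_dataset(config.generator)
    labels = dataset.labels
    result = ExperimentResult(config_hash=config.hash())
    train_idx, test_idx = net_mod.stratified_split(labels, config.train_fraction, config.seed)
    result.split = (train_idx, test_idx)
    logger.info("split: %d train / %d test (config %s)", train_idx.size, test_idx.size,
                result.config_hash)

    if config.band_ablation:
        corrected, _ = msc_correct(dataset.spectra)
        mask = band_mod.score_bands(
            corrected[train_idx], labels[train_idx],
            threshold=config.band_threshold, wavelengths=dataset.wavelengths,
        )
        dataset.spectra = band_mod.ablate(dataset.spectra, mask)
        result.band_mask = mask
        logger.info("band ablation kept %d of %d bands", mask.n_selected, mask.scores.size)

    rep = _representations(dataset)
    rows = []
    for source in config.sources:
        tensors = _source_tensors(rep, source)
        features = _source_features(rep, source)
        for model_name in config.models:
            if model_name == "resnet_rh":
                spec = net_mod.ArchitectureSpec(
                    in_channels=tensors.shape[3], base_channels=config.base_channels
                )
                model = net_mod.build_model(spec, seed=config.seed)
                tc = net_mod.TrainConfig(
                    epochs=config.epochs, batch_size=config.batch_size,
                    learning_rate=config.learning_rate, seed=config.seed,
                    train_fraction=config.train_fraction,
                )
                net_mod.fit(model, tensors[train_idx], labels[train_idx], tc)
                pred, _ = net_mod.predict(model, tensors[test_idx])
            else:
                table = base_mod.FeatureTable(
                    features[train_idx], labels[train_idx], source=source
                )
                est = base_mod.fit_baseline(model_name, table, seed=config.seed)
                pred = est.predict(features[test_idx])
            cm = eval_mod.confusion(labels[test_idx], pred)
            report = eval_mod.metrics(cm)
            result.reports[(source, model_name)] = report
            result.confusions[(source, model_name)] = cm
            rows.append(
                {
                    "source": source,
                    "model": model_name,
                    "accuracy": report.accuracy,
                    "precision": report.macro_precision,
                    "recall": report.macro_recall,
                    "f1": report.macro_f1,
                }
            )
            logger.info("%s / %s: accuracy %.3f", source, model_name, report.accuracy)
    result.summary = (
        pd.DataFrame(rows)
        .set_index(["source", "model"])
        .unstack("model")
        .reindex(list(config.sources))
    )
    if config.outdir:
        _write_outputs(config, result)
    return result


def _write_outputs(config: ExperimentConfig, result: ExperimentResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = result.config_hash
    flat = pd.DataFrame(
        [
            {"source": s, "model": m, **r.to_dict()}
            for (s, m), r in result.reports.items()
        ]
    )
    (outdir / "reports.json").write_text(
        json.dumps({"config_hash": tag, "reports": flat.to_dict(orient="records")},
                   indent=2, default=str)
    )
    result.summary.to_csv(outdir / "summary.csv")
    for (s, m), cm in result.confusions.items():
        np.savetxt(outdir / f"confusion_{s}_{m}.csv", cm, fmt="%d", delimiter=",",
                   header=f"config {tag}; rows=true class, cols=predicted")
        _plot_confusion(cm, outdir / f"confusion_{s}_{m}.png", f"{s} / {m}")
    if result.band_mask is not None:
        (outdir / "band_mask.json").write_text(result.band_mask.to_json())


def _plot_confusion(cm: np.ndarray, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.imshow(cm, cmap="Blues")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(int(cm[i, j])), ha="center", va="center", fontsize=8)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
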