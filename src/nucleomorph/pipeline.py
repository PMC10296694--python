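"""End-to-end orchestration: synth -> segment -> extract -> rank -> bench.

A run is driven by a :class:`PipelineConfig`, writes every intermediate
artifact in a plain standard format (PNG, CSV, JSON) into a run directory,
and serialises the full configuration plus seed into ``manifest.json`` so
any run is reproducible from its manifest alone.

A directory of real PNG/TIFF images with a ``labels.csv`` can replace the
synthetic stage; masks may come either from the segmentation front-end or
from supplied ground-truth instance maps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .bench import CLASSIFIER_NAMES, run_bench
from .features import FEATURE_NAMES, extract_features
from .mrmr import rank_features
from .segmentation import SegmentationParams, segment_nuclei
from .synthetic import (
    ClassSpec,
    ShapeSpec,
    default_benign_spec,
    default_malignant_spec,
    generate_dataset,
    save_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "scatter_export", "extract_table"]

_KNOWN_KEYS = {
    "seed",
    "n_per_class",
    "image_size",
    "benign",
    "malignant",
    "segmentation",
    "masks",
    "intensity_channel",
    "mrmr_bins",
    "classifiers",
    "stages",
    "image_dir",
    "labels_csv",
}


@dataclass
class PipelineConfig:
    """Validated configuration of a full run."""

    seed: int = 0
    n_per_class: int = 50
    image_size: tuple[int, int] = (256, 256)
    benign: ClassSpec = field(default_factory=default_benign_spec)
    malignant: ClassSpec = field(default_factory=default_malignant_spec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    masks: str = "ground_truth"  # or "segmented"
    intensity_channel: str = "luminance"
    mrmr_bins: int = 10
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    stages: tuple[str, ...] = ("synth", "extract", "rank", "bench")
    image_dir: str | None = None   # real-image mode
    labels_csv: str | None = None

    def __post_init__(self) -> None:
        if self.masks not in ("ground_truth", "segmented"):
            raise ValueError("masks must be 'ground_truth' or 'segmented'")
        if self.masks == "ground_truth" and self.image_dir is not None:
            raise ValueError("real-image mode requires masks='segmented'")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("benign", "malignant"):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if isinstance(sub.get("shape"), dict):
                    sub["shape"] = ShapeSpec(**sub["shape"])
                if "n_nuclei_range" in sub:
                    sub["n_nuclei_range"] = tuple(sub["n_nuclei_range"])
                kwargs[key] = ClassSpec(**sub)
        if isinstance(kwargs.get("segmentation"), dict):
            kwargs["segmentation"] = SegmentationParams(**kwargs["segmentation"])
        if "image_size" in kwargs:
            kwargs["image_size"] = tuple(kwargs["image_size"])
        for key in ("classifiers", "stages"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def extract_table(
    images: list[np.ndarray],
    label_maps: list[np.ndarray],
    class_labels: list[str] | None = None,
    names: list[str] | None = None,
    intensity_channel: str = "luminance",
) -> pd.DataFrame:
    """Per-image 33-feature table with ``image`` and ``label`` columns."""
    rows = []
    for i, (img, lmap) in enumerate(zip(images, label_maps)):
        vec = extract_features(img, lmap, intensity_channel)
        row = {"image": names[i] if names else f"img_{i:04d}.png"}
        row.update({name: v for name, v in zip(FEATURE_NAMES, vec)})
        if class_labels is not None:
            row["label"] = class_labels[i]
        rows.append(row)
    return pd.DataFrame(rows)


def _load_real_images(image_dir: str, labels_csv: str):
    table = pd.read_csv(labels_csv)
    images, names, labels = [], [], []
    for _, rec in table.sort_values("filename").iterrows():
        images.append(np.asarray(iio.imread(Path(image_dir) / rec["filename"]))[..., :3])
        names.append(rec["filename"])
        labels.append(rec["label"])
    return images, names, labels


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Writes ``manifest.json``, ``features.csv`` (header
    ``image,f1,...,f33,label``, rows sorted by filename), ``ranking.json``
    and ``report/`` with the per-classifier results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "version": 1}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")

    label_maps: list[np.ndarray]
    if config.image_dir is not None:
        images, names, labels = _load_real_images(config.image_dir, config.labels_csv)
        label_maps = [None] * len(images)
    elif "synth" in config.stages:
        dataset = generate_dataset(
            config.benign, config.malignant, config.n_per_class, config.image_size, config.seed
        )
        save_dataset(dataset, outdir / "data")
        images = dataset.images
        label_maps = dataset.label_maps
        labels = dataset.class_labels
        names = [f"img_{i:04d}.png" for i in range(len(images))]
    else:
        raise ValueError("no image source: enable 'synth' or set image_dir")

    if config.masks == "segmented":
        seg_maps = []
        for name, img in zip(names, images):
            lmap = segment_nuclei(img, config.segmentation)
            n = int(lmap.max())
            logger.info("segment %s: L=%d%s", name, n, " (no nuclei)" if n == 0 else "")
            seg_maps.append(lmap)
        label_maps = seg_maps

    features = extract_table(images, label_maps, labels, names, config.intensity_channel)
    features = features.sort_values("image").reset_index(drop=True)
    cols = ["image", *FEATURE_NAMES, "label"]
    features = features[cols]
    features.to_csv(outdir / "features.csv", index=False, float_format="%.10g")

    if "rank" in config.stages:
        X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
        y = (features["label"] == "malignant").to_numpy().astype(int)
        ranked = rank_features(X, y, n_bins=config.mrmr_bins)
        payload = [
            {"feature": FEATURE_NAMES[i], "score": s}
            for i, s in zip(ranked.order, ranked.scores)
        ]
        (outdir / "ranking.json").write_text(json.dumps(payload, indent=2) + "\n")

    if "bench" in config.stages:
        run_bench(features, list(config.classifiers), config.seed, outdir / "report")

    return outdir


def scatter_export(features: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Tidy (image, feature_x, x, feature_y, y, label) table for plotting
    pairwise feature scatters (e.g. a directional range against the
    bounding-box fill ratio)."""
    known = set(features.columns)
    rows = []
    for fx, fy in pairs:
        for f in (fx, fy):
            if f not in known:
                raise ValueError(f"unknown feature name {f!r}")
        for _, rec in features.iterrows():
            rows.append(
                {
                    "image": rec.get("image", ""),
                    "feature_x": fx,
                    "x": rec[fx],
                    "feature_y": fy,
                    "y": rec[fy],
                    "label": rec.get("label", ""),
                }
            )
    return pd.DataFrame(rows, columns=["image", "feature_x", "x", "feature_y", "y", "label"])
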