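"""Batch and single-image orchestration: measure traits, evaluate results.

The measurement path assembles, for every image, the full 64-trait record
(35 morphological + 7 color + 22 texture) from an RGB image and an instance
label map, and writes one row per image via
:func:`phenotraits.io_formats.write_trait_table`. Undefined traits (empty
scenes, degenerate geometry) are NaN and appear as empty CSV cells, never 0,
so downstream aggregation is not silently biased.

The evaluation path pairs predicted with ground-truth annotations, applies
IoU matching and the metric suite per image, and reports per-image rows plus
batch means; per-trait MAPE and R^2 are added when a manual-measurement
table is supplied.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines
from .colorimetry import COLOR_TRAIT_NAMES, color_traits
from .evaluation import dic, match_instances, mape, precision_recall_f1, r_squared
from .io_formats import (
    TraitRecord,
    load_labelme,
    rasterize_polygons,
    read_image,
    read_label_map,
    write_trait_table,
)
from .morphometry import MORPH_TRAIT_NAMES, aggregate_morphology, measure_instances
from .texture import TEXTURE_TRAIT_NAMES, texture_traits

__all__ = [
    "TRAIT_NAMES",
    "RunConfig",
    "measure_scene",
    "run_measure",
    "run_evaluate",
]

logger = logging.getLogger("phenotraits")

#: The full 64-trait catalog, in fixed order (morphological, color, texture).
TRAIT_NAMES: tuple[str, ...] = (
    MORPH_TRAIT_NAMES + COLOR_TRAIT_NAMES + TEXTURE_TRAIT_NAMES
)

#: Version tag of the trait-column contract, written into output headers.
CATALOG_VERSION = "phenotraits-catalog-v1"


@dataclass
class RunConfig:
    """Configuration of a measurement or evaluation run."""

    inputs: list = field(default_factory=list)  # (image_path, annotation_path|None)
    organ_class: str = "leaf"
    annotation_format: str = "label_map"  # {"label_map", "labelme"}
    output_dir: str = "."
    output_format: str = "csv"  # {"csv", "xlsx"}
    iou_threshold: float = 0.5
    baseline: str = "none"  # {"none", "otsu", "kmeans"}
    seed: int = 0
    per_instance: bool = False
    verbosity: int = 1

    def __post_init__(self):
        if self.organ_class not in ("leaf", "silique"):
            raise ValueError(f"unknown organ class {self.organ_class!r}")


def _load_annotation(path, fmt: str) -> np.ndarray:
    if fmt == "labelme":
        return rasterize_polygons(load_labelme(path))
    return read_label_map(path)


def measure_scene(
    image: np.ndarray,
    instance_map: np.ndarray,
    organ_class: str = "leaf",
    image_id: str = "scene",
) -> TraitRecord:
    """Compute the complete 64-trait record for one image.

    An empty scene (no instances) yields a count of 0, zero totals, and NaN
    for every other trait.
    """
    instances = measure_instances(instance_map)
    traits = aggregate_morphology(instances)
    traits.update(color_traits(image, instance_map))
    traits.update(texture_traits(image, instance_map))
    record = TraitRecord(image_id=image_id, organ_class=organ_class, traits=traits)
    assert list(traits) == list(TRAIT_NAMES)
    return record


def instance_table(instance_map: np.ndarray, image_id: str = "scene") -> pd.DataFrame:
    """Per-instance long-format geometry table (one row per organ)."""
    rows = [
        {
            "image_id": image_id,
            "label": r.label,
            "area": r.area,
            "perimeter": r.perimeter,
            "roundness": r.roundness,
            "ortho_length": r.ortho_length,
            "ortho_width": r.ortho_width,
            "mbb_length": r.mbb_length,
            "mbb_width": r.mbb_width,
            "mbb_area": r.mbb_area,
            "hull_area": r.hull_area,
        }
        for r in measure_instances(instance_map)
    ]
    return pd.DataFrame(rows)


def run_measure(config: RunConfig) -> int:
    """Measure every configured image and write the trait table.

    Returns 0 on success, 1 if any image failed (failed images are skipped
    and recorded in the log).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    instance_frames = []
    failures = 0
    for image_path, ann_path in config.inputs:
        t0 = time.perf_counter()
        image_id = Path(image_path).stem
        try:
            image = read_image(image_path)
            if config.baseline != "none":
                instance_map = baselines.segment_baseline(
                    image, method=config.baseline, seed=config.seed
                )
            elif ann_path is None:
                raise FileNotFoundError(
                    f"no annotation for {image_path} and no baseline selected"
                )
            else:
                instance_map = _load_annotation(ann_path, config.annotation_format)
            if instance_map.shape != image.shape[:2]:
                raise ValueError(
                    f"{image_path}: annotation dimensions {instance_map.shape} "
                    f"differ from image {image.shape[:2]}"
                )
            record = measure_scene(
                image, instance_map, config.organ_class, image_id
            )
            records.append(record)
            if config.per_instance:
                instance_frames.append(instance_table(instance_map, image_id))
            n = int(record.traits["Total Leaf Number"])
            logger.info(
                "%s: %d instances, %.3fs", image_id, n, time.perf_counter() - t0
            )
        except Exception as exc:
            failures += 1
            logger.error("%s: failed (%s)", image_id, exc)
    suffix = "xlsx" if config.output_format == "xlsx" else "csv"
    table_path = out_dir / f"traits_{config.organ_class}.{suffix}"
    write_trait_table(records, table_path, format=config.output_format)
    logger.info("wrote %s (%d rows, %s)", table_path, len(records), CATALOG_VERSION)
    if config.per_instance and instance_frames:
        pd.concat(instance_frames, ignore_index=True).to_csv(
            out_dir / f"instances_{config.organ_class}.csv", index=False
        )
    return 1 if failures else 0


def run_evaluate(
    config: RunConfig,
    truth_paths: list,
    manual_table: str | None = None,
    auto_table: str | None = None,
) -> dict:
    """Evaluate predicted annotations against ground truth, batch-wise.

    ``truth_paths`` pairs with ``config.inputs`` by position: each element is
    the ground-truth annotation for the corresponding input's predicted
    annotation. Returns a report dict with per-image rows and batch means;
    also writes ``metrics.csv`` and ``metrics.json`` to the output directory.
    When ``manual_table`` and ``auto_table`` (CSV trait tables) are supplied,
    per-trait MAPE and R^2 columns are appended to the report.
    """
    if len(truth_paths) != len(config.inputs):
        offenders = abs(len(truth_paths) - len(config.inputs))
        raise ValueError(
            f"every image needs a paired truth annotation ({offenders} unpaired)"
        )
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (image_path, pred_path), truth_path in zip(config.inputs, truth_paths):
        pred = _load_annotation(pred_path, config.annotation_format)
        truth = _load_annotation(truth_path, config.annotation_format)
        m = match_instances(pred, truth, config.iou_threshold)
        p, r, f1 = precision_recall_f1(m)
        rows.append(
            {
                "image_id": Path(image_path).stem,
                "TP": m.TP,
                "FP": m.FP,
                "FN": m.FN,
                "precision": p,
                "recall": r,
                "f1": f1,
                "DiC": dic(m.n_pred, m.n_truth),
            }
        )
    per_image = pd.DataFrame(rows)
    batch = {
        "mean_precision": float(per_image["precision"].mean()),
        "mean_recall": float(per_image["recall"].mean()),
        "mean_f1": float(per_image["f1"].mean()),
        "mean_DiC": float(per_image["DiC"].mean()),
        "n_images": len(rows),
    }
    report = {"per_image": rows, "batch": batch}
    if manual_table is not None and auto_table is not None:
        manual = pd.read_csv(manual_table).set_index("image_id")
        auto = pd.read_csv(auto_table).set_index("image_id")
        shared = [c for c in auto.columns if c in manual.columns]
        agreement = {}
        for col in shared:
            a = auto[col].to_numpy(dtype=float)
            mn = manual.loc[auto.index, col].to_numpy(dtype=float)
            valid = ~(np.isnan(a) | np.isnan(mn))
            a, mn = a[valid], mn[valid]
            entry = {}
            if len(a) >= 1 and (mn != 0).all():
                entry["mape_percent"] = mape(a, mn)
            if len(a) >= 2 and np.var(a) > 0:
                entry["r_squared"] = r_squared(a, mn).r_squared
            if entry:
                agreement[col] = entry
        report["trait_agreement"] = agreement
    per_image.to_csv(out_dir / "metrics.csv", index=False)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
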