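"""End-to-end orchestration: segment -> normalize -> extract -> select -> evaluate.

Per-image failures (e.g. segmentation finding no circle) are recorded in the
run manifest and the image is excluded from the feature table; the cohort
run continues.  All randomness derives from one root seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as iio
from .errors import IristexError, PipelineError
from .evaluation import classifier_registry, stratified_kfold_eval
from .features import FeatureConfig, extract_feature_vector, feature_names
from .normalization import ClaheParams, RoiSpec, crop_heart_roi, enhance_clahe, rubber_sheet
from .segmentation import (
    IrisGeometry,
    default_iris_config,
    default_pupil_config,
    locate_iris,
    locate_pupil,
)
from .selection import relieff_rank, select_top

log = logging.getLogger("iristex")

__all__ = ["PipelineConfig", "PipelineResult", "process_image", "run_pipeline", "run_pipeline_files"]


@dataclass(frozen=True)
class PipelineConfig:
    roi: RoiSpec = RoiSpec()
    clahe: ClaheParams = ClaheParams()
    apply_clahe: bool = True
    features: FeatureConfig = FeatureConfig()
    relieff_k_neighbors: int = 10
    top_k: tuple[int, ...] = (25, 50, 75)
    classifier_names: tuple[str, ...] | None = None  # None = all 22
    n_folds: int = 5
    seed: int = 0
    mask_lids: bool = False


@dataclass(frozen=True)
class PipelineResult:
    features: pd.DataFrame  # 136 feature columns + label
    ranking: object
    reports: dict  # k -> {preset_name -> MetricsReport}
    manifest: pd.DataFrame  # one record per input, including failures


def process_image(image: np.ndarray, config: PipelineConfig | None = None):
    """Segment, unwrap, crop, enhance and featurize one grayscale eye image.

    Returns ``(feature_vector, geometry, roi)``.
    """
    config = config or PipelineConfig()
    pupil = locate_pupil(image, default_pupil_config(image.shape))
    iris = locate_iris(
        image, pupil, default_iris_config(pupil, image.shape, mask_lids=config.mask_lids)
    )
    geometry = IrisGeometry(pupil=pupil, iris=iris)
    norm = rubber_sheet(image, geometry)
    roi = crop_heart_roi(norm, config.roi)
    if config.apply_clahe:
        roi = enhance_clahe(roi, config.clahe)
    fv = extract_feature_vector(roi, config.features)
    return fv, geometry, roi


def run_pipeline(images, labels, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full pipeline over an in-memory cohort.

    ``images`` is a sequence of 2-D uint8 arrays and ``labels`` the parallel
    binary labels.  Evaluates every configured classifier preset on the
    ReliefF top-k subsets.
    """
    config = config or PipelineConfig()
    if len(images) == 0:
        raise ValueError("empty image list")
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")

    rows, kept_labels, records = [], [], []
    for idx, (img, label) in enumerate(zip(images, labels)):
        t0 = time.perf_counter()
        try:
            fv, geometry, _ = process_image(img, config)
            rows.append(fv.values)
            kept_labels.append(int(label))
            records.append(
                dict(index=idx, label=int(label), status="ok", error="",
                     pupil_r=geometry.pupil.r, iris_r=geometry.iris.r,
                     seconds=time.perf_counter() - t0)
            )
        except IristexError as exc:
            log.warning("image %d failed: %s", idx, exc)
            records.append(
                dict(index=idx, label=int(label), status="failed", error=str(exc),
                     pupil_r=np.nan, iris_r=np.nan, seconds=time.perf_counter() - t0)
            )
    if not rows:
        raise PipelineError("every input image failed a pipeline stage")

    X = np.vstack(rows)
    y = np.asarray(kept_labels)
    features = pd.DataFrame(X, columns=list(feature_names()))
    features["label"] = y

    k_neighbors = min(config.relieff_k_neighbors, int(np.bincount(y).min()) - 1)
    ranking = relieff_rank(X, y, k_neighbors=max(1, k_neighbors), seed=config.seed)

    registry = classifier_registry()
    if config.classifier_names is not None:
        registry = [c for c in registry if c.preset_name in config.classifier_names]
    reports: dict[int, dict] = {}
    for k in config.top_k:
        k_eff = min(k, X.shape[1])
        cols = select_top(ranking, k_eff)
        reports[k] = {}
        for clf in registry:
            t0 = time.perf_counter()
            reports[k][clf.preset_name] = stratified_kfold_eval(
                X[:, cols], y, clf, n_folds=config.n_folds, seed=config.seed
            )
            log.info("k=%d %s: %.2fs", k, clf.preset_name, time.perf_counter() - t0)
    return PipelineResult(
        features=features,
        ranking=ranking,
        reports=reports,
        manifest=pd.DataFrame(records),
    )


def run_pipeline_files(manifest_path, config: PipelineConfig | None = None, image_root=None) -> PipelineResult:
    """Run the pipeline from a CSV manifest with ``filename`` and ``label`` columns."""
    from pathlib import Path

    manifest = iio.read_manifest(manifest_path)
    root = Path(image_root) if image_root is not None else Path(manifest_path).parent
    images = [iio.read_image(root / f) for f in manifest["filename"]]
    return run_pipeline(images, manifest["label"].tolist(), config)
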