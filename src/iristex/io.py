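"""Image, feature-table and report I/O."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "read_image",
    "write_image",
    "read_feature_table",
    "write_feature_table",
    "write_report",
    "read_manifest",
]


def read_image(path) -> np.ndarray:
    """Read PNG/JPEG/TIFF as an 8-bit grayscale array.

    RGB inputs are converted by ITU-R 601 luminance weights.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with Image.open(path) as im:
        if im.mode != "L":
            im = im.convert("L")
        return np.asarray(im, dtype=np.uint8)


def write_image(path, image: np.ndarray) -> None:
    img = np.clip(np.rint(np.asarray(image, dtype=np.float64)), 0, 255).astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img).save(path)


def write_feature_table(path, X: np.ndarray, names, labels=None) -> None:
    """CSV with one header row of feature names plus an optional label column."""
    df = pd.DataFrame(np.asarray(X, dtype=np.float64), columns=list(names))
    if labels is not None:
        df["label"] = np.asarray(labels).astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_feature_table(path):
    """Returns (X, names, labels); labels is None without a label column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=np.float64), tuple(df.columns), labels


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return pd.read_csv(path)


def write_report(path, report: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
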