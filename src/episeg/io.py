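"""Reading and writing the pipeline's file formats.

Images are 8-bit RGB TIFF/PNG (converted to float in [0, 1] in memory); masks
are single-channel 8-bit images with 0 = background and 255 = epithelium;
displacement fields are 2-plane 32-bit float TIFFs (row plane first);
correction annotations are GeoJSON-style polygon lists in pixel coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .maskgen import Region

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_field",
    "write_field",
    "read_annotations",
    "write_annotations",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load an RGB image as float (H, W, 3) in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.dtype == np.uint8:
        return arr[..., :3].astype(float) / 255.0
    return np.clip(arr[..., :3].astype(float), 0.0, 1.0)


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    arr = (np.clip(image, 0, 1) * 255).round().astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    return np.asarray(arr) > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    arr = np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def write_field(path: str | Path, field: np.ndarray) -> None:
    """Displacement field as a 2-plane float32 TIFF (row plane, column plane)."""
    tifffile.imwrite(Path(path), field.transpose(2, 0, 1).astype(np.float32),
                     photometric="minisblack")


def read_field(path: str | Path) -> np.ndarray:
    planes = tifffile.imread(Path(path))
    if planes.ndim != 3 or planes.shape[0] != 2:
        raise ValueError(f"expected a 2-plane field TIFF, got shape {planes.shape}")
    return planes.transpose(1, 2, 0).astype(float)


def read_annotations(path: str | Path) -> list[Region]:
    """GeoJSON-style list: ``[{"label": ..., "polygon": [[r, c], ...]}, ...]``."""
    data = json.loads(Path(path).read_text())
    return [Region(polygon=np.asarray(item["polygon"], dtype=float), label=item["label"])
            for item in data]


def write_annotations(path: str | Path, regions: list[Region]) -> None:
    data = [{"label": r.label, "polygon": np.asarray(r.polygon).tolist()} for r in regions]
    Path(path).write_text(json.dumps(data, indent=1))
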