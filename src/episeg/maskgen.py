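"""Binary epithelium reference masks from deconvolved IHC.

The IHC reference-standard pipeline is: colour-deconvolve the stained slide,
sum the epithelial stain channels (CK8/18-DAB plus P63-NovaRED — basal cells
are epithelial too), threshold into a binary mask, clean small errors with
binary closing and opening, and optionally apply manual polygon corrections
for non-specific staining (corpora amylacea, debris) that the stain picks up.

A simple total-optical-density tissue detector is included to separate tissue
from glass background (and from empty, glass-bright lumina).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.draw import polygon as _raster_polygon
from skimage.filters import threshold_otsu
from scipy.ndimage import binary_closing as _closing, binary_opening as _opening
from skimage.morphology import disk

from .stains import ConcentrationMap, rgb_to_od

__all__ = [
    "Region",
    "LABELS",
    "detect_tissue",
    "threshold_channel",
    "morph_clean",
    "apply_corrections",
    "ihc_reference_mask",
]

LABELS = ("epithelium", "background", "artefact")


@dataclass(frozen=True)
class Region:
    """One correction annotation: a simple polygon and its target label.

    ``polygon`` is an ``(N, 2)`` array of (row, col) vertices in pixel
    coordinates; ``artefact`` regions are relabelled to background (they are
    stained debris, not epithelium).
    """

    polygon: np.ndarray
    label: str

    def __post_init__(self):
        poly = np.atleast_2d(np.asarray(self.polygon, dtype=float))
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon must be an (N>=3, 2) array of (row, col) vertices")
        object.__setattr__(self, "polygon", poly)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def _is_simple(poly: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return Polygon([(c, r) for r, c in poly]).is_simple


def detect_tissue(
    image: np.ndarray,
    od_threshold: float = 0.10,
    background_intensity: float = 1.0,
    fill_holes: bool = True,
) -> np.ndarray:
    """Threshold-based tissue/background detector.

    Marks pixels whose summed optical density over the three colour channels
    exceeds ``od_threshold``, then fills enclosed holes.  Glass background and
    empty lumina are near the white point and fall below any positive
    threshold.  (Hole filling is skipped for lumen-aware uses such as
    evaluation exclusion masks.)
    """
    od = rgb_to_od(image, background_intensity)
    tissue = od.sum(axis=2) > od_threshold
    if fill_holes and od_threshold > 0:
        tissue = binary_fill_holes(tissue)
    return tissue


def threshold_channel(
    conc: ConcentrationMap,
    channel_names: str | list[str] = ("dab", "novared"),
    threshold: float = 0.15,
    otsu: bool = False,
) -> np.ndarray:
    """Binary mask from the summed named stain channels.

    Negative concentrations (deconvolution noise) are clipped to zero before
    summation.  ``mask = sum > threshold``; with ``otsu=True`` the threshold is
    instead estimated from the channel histogram, which absorbs slide-to-slide
    stain intensity differences.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    names = [channel_names] if isinstance(channel_names, str) else list(channel_names)
    for name in names:
        if name not in conc.names:
            raise KeyError(f"unknown channel {name!r}; available: {list(conc.names)}")
    total = np.zeros(conc.channels.shape[:2])
    for name in names:
        total += np.clip(conc.channel(name), 0.0, None)
    if otsu:
        threshold = float(threshold_otsu(total))
    return total > threshold


def morph_clean(mask: np.ndarray, closing_radius: int = 1, opening_radius: int = 1) -> np.ndarray:
    """Remove small mask errors: binary closing then opening with disc elements.

    Closing (radius ``closing_radius``) fills cracks and pinholes; the
    subsequent opening (radius ``opening_radius``) removes speckle smaller
    than the disc.  Radius 0 disables the respective operation.  The tile is
    reflect-padded first, so border pixels behave as if the tile were a window
    into a larger slide rather than being eroded against an empty border.
    """
    if closing_radius < 0 or opening_radius < 0:
        raise ValueError("radii must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    pad = 2 * (closing_radius + opening_radius)
    if pad == 0:
        return mask.copy()
    out = np.pad(mask, pad, mode="reflect")
    if closing_radius > 0:
        out = _closing(out, disk(closing_radius))
    if opening_radius > 0:
        out = _opening(out, disk(opening_radius))
    return out[pad:-pad, pad:-pad]


def rasterise_region(region: Region, shape: tuple[int, int]) -> np.ndarray:
    """Boolean footprint of a polygon on the pixel grid (row/col, 0-based,
    pixel-centre rule), clipped to the image bounds."""
    rr, cc = _raster_polygon(region.polygon[:, 0], region.polygon[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def apply_corrections(
    mask: np.ndarray, annotations: list[Region]
) -> tuple[np.ndarray, float]:
    """Overwrite mask pixels inside each annotation polygon with its label.

    Annotations are applied in list order, so later regions win on overlaps.
    ``artefact`` regions become background.  Returns the corrected mask and
    the fraction of pixels whose label changed — the "how much of the tissue
    was relabelled" statistic used to audit a correction campaign.
    """
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    for i, region in enumerate(annotations):
        if not _is_simple(region.polygon):
            raise ValueError(f"annotation {i} is self-intersecting")
        footprint = rasterise_region(region, mask.shape)
        out[footprint] = region.label == "epithelium"
    changed = float(np.mean(out != mask))
    return out, changed


def ihc_reference_mask(
    conc: ConcentrationMap,
    channel_names=("dab", "novared"),
    threshold: float = 0.15,
    closing_radius: int = 1,
    opening_radius: int = 1,
    annotations: list[Region] | None = None,
    otsu: bool = False,
) -> np.ndarray:
    """Full deconvolution-to-reference-mask pipeline: threshold the combined
    epithelium channel, morphologically clean, then apply any corrections."""
    mask = threshold_channel(conc, channel_names, threshold, otsu=otsu)
    mask = morph_clean(mask, closing_radius, opening_radius)
    if annotations:
        mask, _ = apply_corrections(mask, annotations)
    return mask
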