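"""Stain colour model: optical density, colour deconvolution and stain-space augmentation.

Light absorption by histological stains follows the Beer-Lambert law: in
optical-density space (``OD = -log(I / I0)``) the contributions of individual
stains combine linearly, ``OD = M @ c`` with ``M`` the matrix of unit stain
colour vectors and ``c`` the per-stain concentrations.  Colour deconvolution
inverts this mixing to recover one concentration image per stain, which is how
the epithelium channel is extracted from P63/CK8-18 immunohistochemistry.

Stain colour vectors are instrument- and protocol-dependent.  The shipped
defaults are the widely used Ruifrok-Johnston vectors for haematoxylin, eosin
and DAB; the NovaRED vector is a documented red-brown estimate and, like all
vectors here, can be overridden from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainMatrix",
    "ConcentrationMap",
    "STAIN_PRESETS",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "reconstruct",
    "stain_space_augment",
]

#: Intensity floor, as a fraction of the white point, used before taking logs.
#: Caps the maximum representable optical density at -log(1/255) ~ 5.54.
INTENSITY_FLOOR = 1.0 / 255.0


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainMatrix:
    """Unit optical-density colour vectors of up to three stains.

    Parameters
    ----------
    vectors
        Array of shape ``(n_stains, 3)``; each row is the OD direction of one
        stain.  Rows are normalised to unit Euclidean length on construction.
    names
        One label per stain, in row order.
    """

    vectors: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        vecs = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if vecs.shape[1] != 3:
            raise ValueError(f"stain vectors must have 3 components, got shape {vecs.shape}")
        if np.any(vecs < 0):
            raise ValueError("stain OD vector components must be non-negative")
        norms = np.linalg.norm(vecs, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length stain vector")
        object.__setattr__(self, "vectors", vecs / norms[:, None])
        if len(self.names) != vecs.shape[0]:
            raise ValueError("one name required per stain vector")
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_stains(self) -> int:
        return self.vectors.shape[0]

    @property
    def mixing(self) -> np.ndarray:
        """Mixing matrix ``M`` of shape ``(3, n_stains)`` with stains as columns."""
        return self.vectors.T

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.mixing))

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown stain {name!r}; available: {list(self.names)}") from None


@dataclass
class ConcentrationMap:
    """Per-stain concentration images, in OD units.

    ``channels`` has shape ``(H, W, n_stains)``; negative values that arise
    from inverting noisy pixels are preserved here (clipping happens only at
    mask-generation time) so that deconvolution stays linear.
    """

    channels: np.ndarray
    names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError("channels must be H x W x n_stains")
        self.names = tuple(self.names)
        if self.names and len(self.names) != self.channels.shape[2]:
            raise ValueError("channel/name count mismatch")

    def channel(self, name: str) -> np.ndarray:
        return self.channels[..., self.names.index(name)]


# Ruifrok-Johnston vectors for H, E and DAB; NovaRED is a red-brown estimate
# (strong green/blue absorption) — all overridable via config.
_HAEMATOXYLIN = _unit([0.650, 0.704, 0.286])
_EOSIN = _unit([0.072, 0.990, 0.105])
_DAB = _unit([0.268, 0.570, 0.776])
_NOVARED = _unit([0.450, 0.800, 0.397])


def _residual_vector(v1, v2) -> np.ndarray:
    r = np.cross(v1, v2)
    return _unit(np.abs(r))


STAIN_PRESETS: dict[str, StainMatrix] = {
    # IHC pair used for the epithelium reference standard: CK8/18 via DAB
    # (all epithelium, brown) and P63 via NovaRED (basal cells, red).
    "ihc_p63_ck818": StainMatrix(
        np.stack([_HAEMATOXYLIN, _DAB, _NOVARED]),
        ("haematoxylin", "dab", "novared"),
    ),
    # Routine H&E, third channel is the orthogonal residual (Ruifrok's trick
    # to make the 3x3 system invertible).
    "he": StainMatrix(
        np.stack([_HAEMATOXYLIN, _EOSIN, _residual_vector(_HAEMATOXYLIN, _EOSIN)]),
        ("haematoxylin", "eosin", "residual"),
    ),
}


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def rgb_to_od(image: np.ndarray, background_intensity: float | np.ndarray = 1.0) -> np.ndarray:
    """Convert RGB intensities in [0, 1] to optical density.

    ``OD = -log(max(I, floor * I0) / I0)`` per channel, where ``I0`` is the
    white point (``background_intensity``).  The floor avoids ``-log(0)`` and
    caps the OD at ``-log(floor)``.
    """
    image = _check_rgb(image)
    i0 = np.asarray(background_intensity, dtype=float)
    if np.any(i0 <= 0):
        raise ValueError("background intensity must be positive")
    clipped = np.maximum(image, INTENSITY_FLOOR * i0)
    return -np.log(clipped / i0)


def od_to_rgb(od: np.ndarray, background_intensity: float | np.ndarray = 1.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`: ``I = I0 * exp(-OD)``, clipped to [0, 1]."""
    od = np.asarray(od, dtype=float)
    i0 = np.asarray(background_intensity, dtype=float)
    return np.clip(i0 * np.exp(-od), 0.0, 1.0)


def deconvolve(
    image: np.ndarray,
    stains: StainMatrix,
    background_intensity: float | np.ndarray = 1.0,
) -> ConcentrationMap:
    """Unmix an RGB image into per-stain concentration channels.

    Solves ``OD = M @ c`` per pixel by (least-squares) inversion of the stain
    mixing matrix.  Negative concentrations caused by noise or out-of-gamut
    colours are preserved; clip them downstream where a physical quantity is
    required.
    """
    od = rgb_to_od(image, background_intensity)
    m = stains.mixing  # (3, S)
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e8:
        raise np.linalg.LinAlgError(
            f"stain matrix for {list(stains.names)} is singular or near-singular "
            f"(condition number {cond:.3g})"
        )
    pinv = np.linalg.pinv(m)  # (S, 3)
    conc = od.reshape(-1, 3) @ pinv.T
    return ConcentrationMap(conc.reshape(od.shape[0], od.shape[1], stains.n_stains), stains.names)


def reconstruct(
    conc: ConcentrationMap | np.ndarray,
    stains: StainMatrix,
    background_intensity: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Forward Beer-Lambert render: ``I = I0 * exp(-(M @ c))``, clipped to [0, 1]."""
    channels = conc.channels if isinstance(conc, ConcentrationMap) else np.asarray(conc, dtype=float)
    if channels.ndim != 3 or channels.shape[2] != stains.n_stains:
        raise ValueError(
            f"concentration map has {channels.shape[2:]} channels, "
            f"stain matrix defines {stains.n_stains}"
        )
    od = channels.reshape(-1, stains.n_stains) @ stains.mixing.T
    return od_to_rgb(od.reshape(channels.shape[0], channels.shape[1], 3), background_intensity)


def stain_space_augment(
    image: np.ndarray,
    stains: StainMatrix,
    scale_range: tuple[float, float] = (1.0, 1.0),
    shift_range: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | int | None = None,
    channels: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Perturb an image in stain-concentration space.

    Deconvolves the image, applies an independent multiplicative factor drawn
    from ``scale_range`` and additive offset from ``shift_range`` to each
    selected stain channel, and re-renders.  Zero-width ranges at (1, 0)
    return the input unchanged up to round-trip error.  Used for
    haematoxylin-eosin colour-space augmentation during H&E training.
    """
    rng = np.random.default_rng(rng)
    conc = deconvolve(image, stains)
    idx = range(stains.n_stains) if channels is None else [stains.index(c) for c in channels]
    out = conc.channels.copy()
    for k in idx:
        scale = rng.uniform(*sorted(scale_range))
        shift = rng.uniform(*sorted(shift_range))
        out[..., k] = out[..., k] * scale + shift
    return reconstruct(ConcentrationMap(out, stains.names), stains)
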