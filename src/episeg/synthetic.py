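"""Paired-stain synthetic prostate histology with pixel-perfect ground truth.

Generates toy tissue scenes containing the morphologies that make epithelium
segmentation hard in practice: benign glands (epithelial ring with a basal
cell layer around an empty lumen), small malignant glands (no basal layer,
small or absent lumen) and single-cell strands (the poorly differentiated,
grade-5-like growth pattern).  Each scene is rendered twice from the same
geometry — an H&E-like image and a P63/CK8-18 IHC-like image — mimicking a
destain/restain pair of the same physical section.  Non-specific staining
artefacts (corpora-amylacea-like blobs that take up the epithelial stain) can
be injected inside gland lumina, and a smooth random deformation can be
applied to one rendering to emulate the tissue distortion introduced by
restaining and rescanning.

Rendering goes through the Beer-Lambert forward model of :mod:`episeg.stains`,
so colour deconvolution recovers the generating concentrations exactly (up to
the added sensor noise), and every mask is derived from the generating
geometry, not from the pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .stains import STAIN_PRESETS, ConcentrationMap, StainMatrix, reconstruct

__all__ = [
    "SceneConfig",
    "Gland",
    "Artefact",
    "SyntheticScene",
    "StainRendering",
    "generate_scene",
    "scene_masks",
    "render",
    "deform_pair",
    "random_smooth_field",
]


@dataclass(frozen=True)
class SceneConfig:
    """Scene composition knobs.

    Defaults give a 512 x 512 tile at a nominal 0.48 um/px working resolution
    with a mixed benign/malignant morphology; artefacts are opt-in.
    """

    canvas: int = 512
    n_benign: int = 5
    n_small_malignant: int = 8
    n_single_cell: int = 12
    n_artefacts: int = 0
    benign_radius: tuple[float, float] = (32.0, 52.0)
    lumen_fraction: tuple[float, float] = (0.45, 0.62)
    basal_thickness: float = 3.0
    malignant_radius: tuple[float, float] = (9.0, 16.0)
    malignant_lumen_fraction: tuple[float, float] = (0.25, 0.45)
    single_cell_radius: tuple[float, float] = (2.5, 4.5)
    artefact_radius_fraction: tuple[float, float] = (0.30, 0.55)
    noise_sigma: float = 0.012
    resolution_um_per_px: float = 0.48
    max_placement_attempts: int = 2000


@dataclass(frozen=True)
class Gland:
    kind: str  # benign | small_malignant | single_cell
    centre: tuple[float, float]  # (row, col)
    outer_radius: float
    lumen_radius: float  # 0 for single_cell
    basal_thickness: float  # 0 unless benign
    aspect: float  # minor/major axis ratio
    angle: float  # radians
    stain_level: float  # per-gland epithelial stain multiplier


@dataclass(frozen=True)
class Artefact:
    centre: tuple[float, float]
    radius: float
    gland_index: int


@dataclass(frozen=True)
class SyntheticScene:
    config: SceneConfig
    seed: int
    glands: tuple[Gland, ...]
    artefacts: tuple[Artefact, ...]
    tissue_margin: float


@dataclass
class StainRendering:
    """One stain rendering of a scene plus its geometric ground truth."""

    modality: str  # "HE" or "IHC"
    image: np.ndarray  # H x W x 3 in [0, 1]
    concentrations: ConcentrationMap  # noise-free generating concentrations
    stains: StainMatrix
    truth_mask: np.ndarray  # epithelium ground truth (bool)
    lumen_mask: np.ndarray
    tissue_mask: np.ndarray
    resolution_um_per_px: float = 0.48


def _elliptic_radius(rr, cc, gland: Gland) -> np.ndarray:
    """Anisotropic distance from the gland centre, in units where the gland
    boundary sits at ``outer_radius``."""
    dr = rr - gland.centre[0]
    dc = cc - gland.centre[1]
    ca, sa = np.cos(gland.angle), np.sin(gland.angle)
    u = ca * dc + sa * dr
    v = -sa * dc + ca * dr
    return np.hypot(u, v / gland.aspect)


def generate_scene(config: SceneConfig = SceneConfig(), seed: int = 0) -> SyntheticScene:
    """Place non-overlapping glands by rejection sampling; deterministic in ``seed``.

    Raises ``RuntimeError`` if the requested density cannot be placed within
    ``config.max_placement_attempts`` attempts.
    """
    rng = np.random.default_rng(seed)
    margin = 0.06 * config.canvas  # tissue border; outside is glass/background
    placed: list[Gland] = []

    def try_place(kind: str, n: int, radius_range, lumen_frac, basal: float):
        attempts = 0
        need = n
        while need > 0:
            attempts += 1
            if attempts > config.max_placement_attempts:
                raise RuntimeError(
                    f"could not place {need} more {kind!r} glands after "
                    f"{config.max_placement_attempts} attempts; lower the density"
                )
            radius = rng.uniform(*radius_range)
            lo = margin + radius + 2
            hi = config.canvas - margin - radius - 2
            if hi <= lo:
                raise RuntimeError(f"{kind!r} gland radius {radius:.1f} too large for canvas")
            centre = (rng.uniform(lo, hi), rng.uniform(lo, hi))
            ok = all(
                np.hypot(centre[0] - g.centre[0], centre[1] - g.centre[1])
                > radius + g.outer_radius + 3
                for g in placed
            )
            if not ok:
                continue
            placed.append(
                Gland(
                    kind=kind,
                    centre=centre,
                    outer_radius=radius,
                    lumen_radius=radius * rng.uniform(*lumen_frac) if lumen_frac else 0.0,
                    basal_thickness=basal,
                    aspect=rng.uniform(0.75, 1.0),
                    angle=rng.uniform(0, np.pi),
                    stain_level=rng.uniform(0.85, 1.15),
                )
            )
            need -= 1

    try_place("benign", config.n_benign, config.benign_radius, config.lumen_fraction,
              config.basal_thickness)
    try_place("small_malignant", config.n_small_malignant, config.malignant_radius,
              config.malignant_lumen_fraction, 0.0)
    try_place("single_cell", config.n_single_cell, config.single_cell_radius, None, 0.0)

    artefacts: list[Artefact] = []
    lumened = [i for i, g in enumerate(placed) if g.kind == "benign" and g.lumen_radius > 4]
    for _ in range(config.n_artefacts):
        if not lumened:
            break
        i = int(rng.choice(lumened))
        g = placed[i]
        radius = g.lumen_radius * rng.uniform(*config.artefact_radius_fraction)
        # keep the blob strictly inside the lumen
        max_off = max(g.lumen_radius * g.aspect - radius - 1, 0.0)
        angle = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0, max_off)
        centre = (g.centre[0] + off * np.sin(angle), g.centre[1] + off * np.cos(angle))
        artefacts.append(Artefact(centre=centre, radius=radius, gland_index=i))

    return SyntheticScene(
        config=config, seed=seed, glands=tuple(placed), artefacts=tuple(artefacts),
        tissue_margin=margin,
    )


def scene_masks(scene: SyntheticScene) -> dict[str, np.ndarray]:
    """Rasterise the scene geometry into boolean masks.

    Returns ``epithelium`` (the segmentation ground truth: gland rings, basal
    layers and single cells; excludes lumina, stroma and artefact blobs),
    ``lumen``, ``basal``, ``artefact`` and the overall ``tissue`` footprint.
    """
    n = scene.config.canvas
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    epithelium = np.zeros((n, n), dtype=bool)
    lumen = np.zeros((n, n), dtype=bool)
    basal = np.zeros((n, n), dtype=bool)
    for g in scene.glands:
        d = _elliptic_radius(rr, cc, g)
        if g.kind == "single_cell":
            epithelium |= d <= g.outer_radius
            continue
        ring = (d <= g.outer_radius) & (d > g.lumen_radius)
        epithelium |= ring
        lumen |= d <= g.lumen_radius
        if g.basal_thickness > 0:
            basal |= ring & (d > g.outer_radius - g.basal_thickness)
    artefact = np.zeros((n, n), dtype=bool)
    for a in scene.artefacts:
        artefact |= np.hypot(rr - a.centre[0], cc - a.centre[1]) <= a.radius
    artefact &= lumen
    m = scene.tissue_margin
    tissue = (rr >= m) & (rr < n - m) & (cc >= m) & (cc < n - m)
    tissue &= ~(lumen & ~artefact)  # empty lumina are glass-bright, like background
    return {
        "epithelium": epithelium,
        "lumen": lumen,
        "basal": basal,
        "artefact": artefact,
        "tissue": tissue,
    }


def _stamp_nuclei(shape, centres, radius, rng) -> np.ndarray:
    """Boolean map of small disks (cell nuclei) at the given centres."""
    out = np.zeros(shape, dtype=bool)
    n = shape[0]
    for r0, c0 in centres:
        rad = radius * rng.uniform(0.75, 1.25)
        ir, ic = int(round(r0)), int(round(c0))
        k = int(np.ceil(rad))
        rlo, rhi = max(ir - k, 0), min(ir + k + 1, n)
        clo, chi = max(ic - k, 0), min(ic + k + 1, shape[1])
        if rlo >= rhi or clo >= chi:
            continue
        sub_r, sub_c = np.mgrid[rlo:rhi, clo:chi]
        out[rlo:rhi, clo:chi] |= np.hypot(sub_r - r0, sub_c - c0) <= rad
    return out


def _sample_in_mask(mask: np.ndarray, count: int, rng) -> np.ndarray:
    idx = np.flatnonzero(mask)
    if idx.size == 0 or count == 0:
        return np.empty((0, 2))
    pick = rng.choice(idx, size=min(count, idx.size), replace=False)
    return np.stack(np.unravel_index(pick, mask.shape), axis=1).astype(float)


def render(scene: SyntheticScene, modality: str, seed: int | None = None) -> StainRendering:
    """Render one stain modality of a scene via the Beer-Lambert forward model.

    IHC: epithelial cytoplasm carries DAB (CK8/18), basal rings carry NovaRED
    (P63), nuclei carry haematoxylin; artefact blobs take up DAB despite not
    being epithelium.  H&E: nuclei carry haematoxylin, epithelial cytoplasm and
    stroma carry eosin at different levels.  Additive Gaussian sensor noise is
    applied after rendering; the returned concentration map is noise-free.
    """
    if modality not in ("HE", "IHC"):
        raise ValueError(f"unsupported modality {modality!r}")
    cfg = scene.config
    rng = np.random.default_rng(scene.seed + 1 if seed is None else seed)
    masks = scene_masks(scene)
    n = cfg.canvas
    epi, lum, bas, art, tis = (masks[k] for k in ("epithelium", "lumen", "basal",
                                                  "artefact", "tissue"))
    stroma = tis & ~epi & ~art

    # shared nuclear geometry: dense in epithelium, sparse in stroma
    epi_n = _sample_in_mask(epi, max(int(epi.sum() / 220), 1), rng)
    str_n = _sample_in_mask(stroma, max(int(stroma.sum() / 900), 1), rng)
    nuclei = _stamp_nuclei((n, n), np.vstack([epi_n, str_n]), 2.2, rng)

    gland_level = np.zeros((n, n))
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    for g in scene.glands:
        d = _elliptic_radius(rr, cc, g)
        inside = (d <= g.outer_radius) & ((d > g.lumen_radius) | (g.kind == "single_cell"))
        gland_level[inside] = g.stain_level

    # fibrous stroma texture: the same physical collagen structure shows up in
    # both renderings (eosin in H&E, faint haematoxylin counterstain in IHC),
    # so it is drawn from the scene seed, not the modality seed
    trng = np.random.default_rng(scene.seed + 7)
    texture = gaussian_filter(trng.standard_normal((n, n)), 6.0)
    texture = (texture - texture.min()) / (np.ptp(texture) + 1e-12)

    conc = np.zeros((n, n, 3))
    if modality == "IHC":
        stains = STAIN_PRESETS["ihc_p63_ck818"]
        conc[..., 0] = np.where(nuclei & tis, 0.75, 0.0)
        conc[..., 0] += np.where(stroma, 0.05 + 0.12 * texture, 0.0)
        conc[..., 1] = np.where(epi, 0.85 * gland_level, 0.0)  # DAB on all epithelium
        conc[..., 1] += np.where(art, 0.70, 0.0)  # non-specific staining of debris
        conc[..., 2] = np.where(bas, 0.90, 0.0)  # NovaRED on basal layer
    else:
        stains = STAIN_PRESETS["he"]
        conc[..., 0] = np.where(nuclei & tis, 0.95, 0.0)
        conc[..., 1] = np.where(epi, 0.40 * gland_level, 0.0)
        conc[..., 1] += np.where(stroma, 0.18 + 0.22 * texture, 0.0)
        conc[..., 1] += np.where(art, 0.30, 0.0)

    cmap = ConcentrationMap(conc, stains.names)
    image = reconstruct(cmap, stains)
    if cfg.noise_sigma > 0:
        image = np.clip(image + rng.normal(0, cfg.noise_sigma, image.shape), 0.0, 1.0)

    return StainRendering(
        modality=modality, image=image, concentrations=cmap, stains=stains,
        truth_mask=epi, lumen_mask=lum, tissue_mask=tis,
        resolution_um_per_px=cfg.resolution_um_per_px,
    )


def random_smooth_field(
    shape: tuple[int, int],
    max_displacement: float,
    smoothness: float = 24.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Smooth random displacement field of shape ``(H, W, 2)`` whose maximum
    magnitude equals ``max_displacement`` pixels."""
    rng = np.random.default_rng(rng)
    if max_displacement == 0:
        return np.zeros(shape + (2,))
    field = np.stack(
        [gaussian_filter(rng.standard_normal(shape), smoothness) for _ in range(2)], axis=-1
    )
    mag = np.hypot(field[..., 0], field[..., 1]).max()
    if mag > 0:
        field *= max_displacement / mag
    return field


def _warp_backward(arr: np.ndarray, field: np.ndarray, order: int, cval: float) -> np.ndarray:
    h, w = arr.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    coords = [rr + field[..., 0], cc + field[..., 1]]
    if arr.ndim == 2:
        return map_coordinates(arr.astype(float), coords, order=order, mode="constant", cval=cval)
    return np.stack(
        [map_coordinates(arr[..., k], coords, order=order, mode="constant", cval=cval)
         for k in range(arr.shape[2])], axis=-1,
    )


def deform_pair(
    rendering: StainRendering,
    max_displacement: float = 5.0,
    smoothness: float = 24.0,
    seed: int | None = 0,
) -> tuple[StainRendering, np.ndarray]:
    """Apply a smooth random deformation to a rendering, emulating restaining.

    Returns the warped rendering and the backward sampling field ``u`` that was
    applied: ``warped(x) = original(x + u(x))``.  A registration that takes the
    warped rendering as the moving image therefore recovers (approximately) the
    inverse of ``u``; see ``registration.invert_field``.
    """
    field = random_smooth_field(rendering.image.shape[:2], max_displacement, smoothness, seed)
    warped = dataclasses.replace(
        rendering,
        image=np.clip(_warp_backward(rendering.image, field, order=1, cval=1.0), 0.0, 1.0),
        truth_mask=_warp_backward(rendering.truth_mask, field, order=0, cval=0.0).astype(bool),
        lumen_mask=_warp_backward(rendering.lumen_mask, field, order=0, cval=0.0).astype(bool),
        tissue_mask=_warp_backward(rendering.tissue_mask, field, order=0, cval=0.0).astype(bool),
    )
    return warped, field
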