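"""Multimodal H&E-to-IHC registration: NGF distance, curvature regularisation.

A destained/restained slide pair shows the same tissue in two different colour
renderings, so intensity-based similarity fails; the Normalised Gradient
Fields (NGF) distance instead scores the *alignment of image gradients* and is
insensitive to the intensity relationship between the modalities.  The
pipeline follows the classical chain

    grayscale -> affine pre-alignment -> nonparametric (NGF + curvature)
    -> patch-wise refinement with optimised merging

All displacement fields use the backward-mapping convention: ``field[r, c]``
holds the (row, col) offset added to a fixed-frame pixel centre to obtain the
moving-frame sample position.  Optimisation is plain first-order descent with
Armijo backtracking, so the objective never increases across accepted steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.color import rgb2gray
from skimage.transform import rescale, resize

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "to_grayscale",
    "ngf_distance",
    "curvature_energy",
    "affine_register",
    "nonparametric_register",
    "patch_register_merge",
    "register_pair",
    "warp",
    "field_from_affine",
    "invert_field",
    "displacement_error",
]

IDENTITY_AFFINE = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])


@dataclass
class RegistrationConfig:
    """Knobs of the registration chain.

    ``ngf_epsilon=None`` uses 1% of the fixed image's intensity range at each
    pyramid level (the edge parameter separates real gradients from noise).
    ``curvature_weight`` trades data fit against deformation smoothness.
    """

    ngf_epsilon: float | None = None
    curvature_weight: float = 30.0
    smoothing_sigma: float = 0.5
    update_smoothing_sigma: float = 4.0
    pyramid_levels: int = 4
    min_level_size: int = 32
    max_iterations: int = 100
    affine_max_iterations: int = 60
    patch_size: int = 512
    patch_overlap: int = 128
    merge_weight: float = 1.0
    tol: float = 1e-6
    #: dense descent stops when max |gradient| * n_pixels falls below this
    #: (the mean-normalised NGF gradient scales as 1/n_pixels)
    grad_floor: float = 0.1

    def __post_init__(self):
        if self.patch_overlap >= self.patch_size:
            raise ValueError("patch_overlap must be smaller than patch_size")
        if self.pyramid_levels < 1 or self.max_iterations < 1:
            raise ValueError("pyramid_levels and max_iterations must be >= 1")
        if self.curvature_weight < 0:
            raise ValueError("curvature_weight must be >= 0")


@dataclass
class RegistrationResult:
    affine: np.ndarray
    field: np.ndarray
    final_distance: float
    per_level_distances: list = _dc_field(default_factory=list)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance conversion (ITU-R 601/709 weights as used by scikit-image)."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected RGB or grayscale image, got shape {image.shape}")
    return rgb2gray(image)


def _gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.gradient(img.astype(float))


def ngf_distance(fixed: np.ndarray, moving: np.ndarray, epsilon: float = 0.01) -> float:
    """Normalised Gradient Fields distance in [0, 1].

    ``D = mean(1 - <gF, gM>^2 / ((|gF|^2 + eps^2)(|gM|^2 + eps^2)))``.
    Zero when gradients are everywhere parallel and well above ``epsilon``;
    1 for a pair of constant images.  Symmetric in its two arguments.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    gfr, gfc = _gradients(fixed)
    gmr, gmc = _gradients(moving)
    inner = gfr * gmr + gfc * gmc
    nf = gfr**2 + gfc**2 + epsilon**2
    nm = gmr**2 + gmc**2 + epsilon**2
    return float(np.mean(1.0 - inner**2 / (nf * nm)))


def _laplacian(u: np.ndarray) -> np.ndarray:
    """5-point Laplacian with linear-extrapolation boundary handling, so that
    affine (linear) fields have exactly zero curvature everywhere."""
    p = np.empty((u.shape[0] + 2, u.shape[1] + 2))
    p[1:-1, 1:-1] = u
    p[0, 1:-1] = 2 * u[0] - u[1]
    p[-1, 1:-1] = 2 * u[-1] - u[-2]
    p[1:-1, 0] = 2 * u[:, 0] - u[:, 1]
    p[1:-1, -1] = 2 * u[:, -1] - u[:, -2]
    p[0, 0] = p[0, 1] + p[1, 0] - p[1, 1]
    p[0, -1] = p[0, -2] + p[1, -1] - p[1, -2]
    p[-1, 0] = p[-2, 0] + p[-1, 1] - p[-2, 1]
    p[-1, -1] = p[-1, -2] + p[-2, -1] - p[-2, -2]
    return p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4 * u


def curvature_energy(field: np.ndarray) -> float:
    """Curvature regulariser ``S = 1/2 * mean(|Lap u|^2)`` summed over the two
    displacement components.  Exactly zero for affine fields."""
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise ValueError("displacement field contains non-finite values")
    return 0.5 * sum(float(np.mean(_laplacian(field[..., k]) ** 2)) for k in range(2))


def field_from_affine(params: np.ndarray, shape: tuple[int, int], scale: float = 1.0) -> np.ndarray:
    """Dense displacement field of the affine map ``x -> A (x - c) + c + t``
    about the image centre ``c``; ``scale`` rescales full-resolution parameters
    to a pyramid level (translations divide by the scale)."""
    a11, a12, a21, a22, tr, tc = np.asarray(params, dtype=float)
    h, w = shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rr, cc_ = np.mgrid[0:h, 0:w].astype(float)
    dr = rr - cr
    dc = cc_ - cc
    ur = a11 * dr + a12 * dc - dr + tr / scale
    uc = a21 * dr + a22 * dc - dc + tc / scale
    return np.stack([ur, uc], axis=-1)


def warp(
    arr: np.ndarray,
    field: np.ndarray,
    interpolation: str = "linear",
    background: float = 0.0,
) -> np.ndarray:
    """Resample an image or mask into the fixed frame along a backward field.

    ``interpolation`` is ``"linear"`` for images and ``"nearest"`` for masks
    (masks stay binary); samples falling outside the moving image take the
    ``background`` value.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    order = 1 if interpolation == "linear" else 0
    arr = np.asarray(arr)
    was_bool = arr.dtype == bool
    h, w = field.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    coords = [rr + field[..., 0], cc + field[..., 1]]

    def _one(plane):
        return map_coordinates(plane.astype(float), coords, order=order,
                               mode="constant", cval=background)

    out = (_one(arr) if arr.ndim == 2
           else np.stack([_one(arr[..., k]) for k in range(arr.shape[2])], axis=-1))
    return out > 0.5 if was_bool else out


def _warp_nearest_edge(img: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Internal warp with edge-clamped sampling (no constant background seam,
    which would create spurious gradients during optimisation)."""
    h, w = field.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    return map_coordinates(img, [rr + field[..., 0], cc + field[..., 1]],
                           order=1, mode="nearest")


def _preprocess(img: np.ndarray, config: RegistrationConfig) -> np.ndarray:
    """Grayscale + light Gaussian denoising: NGF scores gradient *directions*,
    so uncorrelated sensor noise would otherwise dominate at fine scales."""
    img = to_grayscale(img)
    if config.smoothing_sigma > 0:
        img = gaussian_filter(img, config.smoothing_sigma)
    return img


def _pyramid(img: np.ndarray, levels: int, min_size: int) -> list[np.ndarray]:
    """Finest-first Gaussian pyramid, stopping before any side gets smaller
    than ``min_size``."""
    out = [img.astype(float)]
    for _ in range(levels - 1):
        nxt = rescale(out[-1], 0.5, anti_aliasing=True)
        if min(nxt.shape) < min_size:
            break
        out.append(nxt)
    return out


def _epsilon_for(fixed_level: np.ndarray, config: RegistrationConfig) -> float:
    if config.ngf_epsilon is not None:
        return config.ngf_epsilon
    return max(0.01 * float(np.ptp(fixed_level)), 1e-6)


def _ngf_gradient_wrt_field(fixed, moving, field, epsilon, grad_moving):
    """Analytic gradient of the NGF distance with respect to the displacement
    field (chain rule through the warped moving image)."""
    mw = _warp_nearest_edge(moving, field)
    gfr, gfc = _gradients(fixed)
    gmr, gmc = _gradients(mw)
    inner = gfr * gmr + gfc * gmc
    nf = gfr**2 + gfc**2 + epsilon**2
    nm = gmr**2 + gmc**2 + epsilon**2
    n = fixed.size
    # dD/dgM components
    common = 2.0 * inner / (nf * nm * n)
    pr = -common * gfr + common * inner / nm * gmr
    pc = -common * gfc + common * inner / nm * gmc
    # dD/dMw = -div(P)  (adjoint of the gradient operator, up to boundary terms)
    ddm = -(np.gradient(pr, axis=0) + np.gradient(pc, axis=1))
    # dMw/du = spatial gradient of the moving image at the sample positions
    h, w = field.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    coords = [rr + field[..., 0], cc + field[..., 1]]
    gm_r = map_coordinates(grad_moving[0], coords, order=1, mode="nearest")
    gm_c = map_coordinates(grad_moving[1], coords, order=1, mode="nearest")
    return np.stack([ddm * gm_r, ddm * gm_c], axis=-1)


def _descend(objective, gradient, x0, max_iterations, tol, max_step=4.0, gmax_floor=0.0):
    """Armijo-backtracking gradient descent; accepts only improving steps.

    The search direction is the max-norm-normalised negative gradient, so the
    step length is directly the largest parameter (displacement) update in its
    native units; steps start at 1 and adapt between ``tol``-scale and
    ``max_step``.
    """
    x = x0
    j = objective(x)
    history = [j]
    step = 1.0
    stall = 0
    for _ in range(max_iterations):
        g = gradient(x)
        gmax = float(np.max(np.abs(g)))
        if gmax <= gmax_floor:
            # negligible gradient: stepping further would only chase
            # resampling/discretisation artifacts of the objective
            break
        d = g / gmax
        slope = float(np.sum(g * d))  # directional derivative along -d
        accepted = False
        for _ in range(25):
            cand = x - step * d
            jc = objective(cand)
            if jc < j - 1e-4 * step * slope:
                accepted = True
                break
            step *= 0.5
            if step < 1e-4:
                break
        if not accepted:
            break
        improvement = j - jc
        x, j = cand, jc
        history.append(j)
        step = min(step * 1.5, max_step)
        stall = stall + 1 if improvement < tol * max(abs(j), 1.0) else 0
        if stall >= 3:
            break
    return x, j, history


def affine_register(
    fixed: np.ndarray, moving: np.ndarray, config: RegistrationConfig | None = None
) -> np.ndarray:
    """Affine pre-alignment minimising the NGF distance over a pyramid.

    Returns six parameters ``(a11, a12, a21, a22, t_row, t_col)`` of the
    backward map about the image centre.  A coarse translation sweep at the
    coarsest level guards against local minima; the identity is returned if
    nothing improves on it.
    """
    config = config or RegistrationConfig()
    fixed = _preprocess(fixed, config)
    moving = _preprocess(moving, config)
    pyr_f = _pyramid(fixed, config.pyramid_levels, config.min_level_size)
    pyr_m = _pyramid(moving, config.pyramid_levels, config.min_level_size)
    params = IDENTITY_AFFINE.copy()

    for level in range(len(pyr_f) - 1, -1, -1):
        f, m = pyr_f[level], pyr_m[level]
        scale = 2.0**level
        eps = _epsilon_for(f, config)

        def obj(p):
            return ngf_distance(f, _warp_nearest_edge(m, field_from_affine(p, f.shape, scale)), eps)

        if level == len(pyr_f) - 1:
            # coarse translation sweep (in coarsest-level pixels)
            best = obj(params)
            for dr in range(-8, 9, 2):
                for dc in range(-8, 9, 2):
                    cand = params.copy()
                    cand[4] += dr * scale
                    cand[5] += dc * scale
                    val = obj(cand)
                    if val < best:
                        best, params = val, cand

        deltas = np.array([1e-3, 1e-3, 1e-3, 1e-3, 0.1 * scale, 0.1 * scale])

        def grad(p):
            g = np.zeros(6)
            for i in range(6):
                e = np.zeros(6)
                e[i] = deltas[i]
                g[i] = (obj(p + e) - obj(p - e)) / (2 * deltas[i])
            # rescale to comparable units
            return g * deltas
        params, _, hist = _descend(obj, grad, params, config.affine_max_iterations, config.tol)
        if len(hist) <= 1 and level == 0:
            warnings.warn("affine registration made no progress at the finest level",
                          stacklevel=2)

    # accept-only-improvement at the finest level
    f, m = pyr_f[0], pyr_m[0]
    eps = _epsilon_for(f, config)
    d_id = ngf_distance(f, m, eps)
    d_fit = ngf_distance(f, _warp_nearest_edge(m, field_from_affine(params, f.shape)), eps)
    return params if d_fit < d_id else IDENTITY_AFFINE.copy()


def nonparametric_register(
    fixed: np.ndarray,
    moving: np.ndarray,
    init: np.ndarray | None = None,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Dense deformable registration minimising ``NGF + alpha * curvature``.

    ``init`` may be six affine parameters, a dense ``(H, W, 2)`` field, or
    ``None`` (identity).  Multi-resolution first-order descent; within a level
    only improving steps are accepted, so the final distance never exceeds the
    initial distance at the finest level.
    """
    config = config or RegistrationConfig()
    fixed = _preprocess(fixed, config)
    moving = _preprocess(moving, config)
    pyr_f = _pyramid(fixed, config.pyramid_levels, config.min_level_size)
    pyr_m = _pyramid(moving, config.pyramid_levels, config.min_level_size)
    alpha = config.curvature_weight

    affine = IDENTITY_AFFINE.copy()
    field = None
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape == (6,):
            affine = init
        elif init.ndim == 3 and init.shape[:2] == fixed.shape and init.shape[2] == 2:
            field = init
        else:
            raise ValueError("init must be 6 affine parameters or an (H, W, 2) field")

    per_level = []
    u = None
    for level in range(len(pyr_f) - 1, -1, -1):
        f, m = pyr_f[level], pyr_m[level]
        scale = 2.0**level
        eps = _epsilon_for(f, config)
        if u is None:
            if field is not None:
                u = (resize(field, f.shape + (2,), order=1, anti_aliasing=False)
                     / scale)
            else:
                u = field_from_affine(affine, f.shape, scale)
        grad_m = _gradients(m)

        def obj(uu):
            return (ngf_distance(f, _warp_nearest_edge(m, uu), eps)
                    + alpha * curvature_energy(uu))

        def grad(uu):
            g = _ngf_gradient_wrt_field(f, m, uu, eps, grad_m)
            if alpha > 0:
                n = uu[..., 0].size
                for k in range(2):
                    g[..., k] += alpha * _laplacian(_laplacian(uu[..., k])) / n
            if config.update_smoothing_sigma > 0:
                # Sobolev-metric descent: spatially coherent updates avoid the
                # incoherent local minima of the raw pointwise gradient
                g = np.stack(
                    [gaussian_filter(g[..., k], config.update_smoothing_sigma)
                     for k in range(2)], axis=-1,
                )
            return g

        u, j, _ = _descend(obj, grad, u, config.max_iterations, config.tol,
                           gmax_floor=config.grad_floor / u[..., 0].size)
        per_level.append(float(ngf_distance(f, _warp_nearest_edge(m, u), eps)))
        if level > 0:
            nxt_shape = pyr_f[level - 1].shape
            u = resize(u, nxt_shape + (2,), order=1, anti_aliasing=False)
            u *= [nxt_shape[0] / f.shape[0], nxt_shape[1] / f.shape[1]]

    final = float(ngf_distance(pyr_f[0], _warp_nearest_edge(pyr_m[0], u),
                               _epsilon_for(pyr_f[0], config)))
    return RegistrationResult(affine=affine, field=u, final_distance=final,
                              per_level_distances=per_level)


def _patch_grid(length: int, size: int, overlap: int) -> list[tuple[int, int]]:
    if size >= length:
        return [(0, length)]
    stride = size - overlap
    starts = list(range(0, length - size, stride)) + [length - size]
    return [(s, s + size) for s in dict.fromkeys(starts)]


def _cosine_window(h: int, w: int) -> np.ndarray:
    wr = np.hanning(h + 2)[1:-1]
    wc = np.hanning(w + 2)[1:-1]
    return np.outer(wr, wc) + 1e-6


def patch_register_merge(
    fixed: np.ndarray,
    moving: np.ndarray,
    init_field: np.ndarray,
    config: RegistrationConfig | None = None,
) -> np.ndarray:
    """Patch-wise deformable refinement with optimised merging.

    Each patch of the fixed image is registered independently (initialised
    from ``init_field``).  The merged field minimises

        sum_p  w_p |phi - phi_p|^2   +   mu * sum_x v(x) |Lap phi(x)|^2

    where ``w_p`` are smooth (raised-cosine) patch windows and ``v`` is the
    local inter-patch disagreement (weighted variance of the patch fields).
    Where patches agree — in particular with a single patch, or identical
    overlapping patches — the data term pins the solution to the common field
    exactly; curvature smoothing acts only in the overlap regions where the
    patch solutions disagree.
    """
    config = config or RegistrationConfig()
    # grayscale only: the per-patch registrations do their own denoising
    fixed = to_grayscale(fixed)
    moving = to_grayscale(moving)
    h, w = fixed.shape
    rows = _patch_grid(h, config.patch_size, config.patch_overlap)
    cols = _patch_grid(w, config.patch_size, config.patch_overlap)
    if min(rows[0][1] - rows[0][0], cols[0][1] - cols[0][0]) < config.min_level_size:
        raise ValueError(
            f"patch size {config.patch_size} is below the minimum pyramid level size "
            f"{config.min_level_size}"
        )

    if len(rows) == 1 and len(cols) == 1:
        # degenerate grid: the single patch *is* the image
        return nonparametric_register(fixed, moving, init=init_field, config=config).field

    wsum = np.zeros((h, w))
    fsum = np.zeros((h, w, 2))
    sqsum = np.zeros((h, w))
    patches = []
    for r0, r1 in rows:
        for c0, c1 in cols:
            sub_init = init_field[r0:r1, c0:c1].copy()
            res = nonparametric_register(fixed[r0:r1, c0:c1], moving[r0:r1, c0:c1],
                                         init=sub_init, config=config)
            win = _cosine_window(r1 - r0, c1 - c0)
            patches.append(((r0, r1, c0, c1), res.field, win))
            wsum[r0:r1, c0:c1] += win
            fsum[r0:r1, c0:c1] += win[..., None] * res.field
    blend = fsum / wsum[..., None]
    for (r0, r1, c0, c1), pf, win in patches:
        dev = pf - blend[r0:r1, c0:c1]
        sqsum[r0:r1, c0:c1] += win * np.sum(dev**2, axis=-1)
    variance = sqsum / wsum  # zero wherever patch fields agree

    if config.merge_weight <= 0 or variance.max() == 0:
        return blend

    mu = config.merge_weight

    def obj(phi):
        lap = sum(variance * _laplacian(phi[..., k]) ** 2 for k in range(2))
        return float(0.5 * np.sum(wsum[..., None] * (phi - blend) ** 2)
                     + 0.5 * mu * np.sum(lap))

    def grad(phi):
        g = wsum[..., None] * (phi - blend)
        for k in range(2):
            g[..., k] += mu * _laplacian(variance * _laplacian(phi[..., k]))
        return g

    merged, _, _ = _descend(obj, grad, blend, 200, 1e-10)
    return merged


def register_pair(
    fixed: np.ndarray, moving: np.ndarray, config: RegistrationConfig | None = None
) -> RegistrationResult:
    """Full chain: grayscale, affine, nonparametric, patch-wise refinement."""
    config = config or RegistrationConfig()
    affine = affine_register(fixed, moving, config)
    res = nonparametric_register(fixed, moving, init=affine, config=config)
    field = patch_register_merge(fixed, moving, res.field, config)
    f = _preprocess(fixed, config)
    m = _preprocess(moving, config)
    eps = _epsilon_for(f, config)
    final = float(ngf_distance(f, _warp_nearest_edge(m, field), eps))
    if final > res.final_distance:  # keep the better of the two stages
        field, final = res.field, res.final_distance
    return RegistrationResult(affine=affine, field=field, final_distance=final,
                              per_level_distances=res.per_level_distances)


def invert_field(field: np.ndarray, iterations: int = 30) -> np.ndarray:
    """Fixed-point inversion of a backward displacement field: returns ``v``
    with ``v(x) = -u(x + v(x))``, so warping by ``v`` undoes warping by ``u``
    (valid for small, smooth fields)."""
    h, w = field.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    v = np.zeros_like(field)
    for _ in range(iterations):
        coords = [rr + v[..., 0], cc + v[..., 1]]
        v = -np.stack(
            [map_coordinates(field[..., k], coords, order=1, mode="nearest")
             for k in range(2)], axis=-1,
        )
    return v


def displacement_error(
    recovered: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Mean Euclidean displacement error, optionally restricted to a mask."""
    diff = np.hypot(recovered[..., 0] - truth[..., 0], recovered[..., 1] - truth[..., 1])
    return float(diff[mask].mean() if mask is not None else diff.mean())
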