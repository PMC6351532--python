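"""Desk-scale end-to-end experiments mirroring the two-stage pipeline.

These experiments run the whole chain on synthetic paired-stain tiles at
sizes a single CPU can handle in minutes: the IHC rendering is deconvolved
and thresholded into reference masks, the masks are carried into the (slightly
deformed) H&E frame, a small U-Net is trained on H&E patches against those
masks, and held-out tiles are scored against the geometric ground truth.

Two protocols are provided:

* :func:`two_stage_toy` — the headline run: depth-3 / 8-filter net, 64
  patches of 128 x 128, pooled F1 on held-out tiles.
* :func:`corrected_vs_corrupted` — the supervision-quality comparison: labels
  corrupted by non-specific staining artefacts versus labels with the
  artefact regions corrected, identical nets and seeds otherwise; repeated
  over seeds, reporting held-out F1 per arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluate, maskgen, registration, stains, synthetic, training, unet

__all__ = ["ToyResult", "two_stage_toy", "corrected_vs_corrupted", "toy_scene_config"]


def toy_scene_config(n_artefacts: int = 0) -> synthetic.SceneConfig:
    """256 px scenes with the gland mix scaled to fit several glands per tile."""
    return synthetic.SceneConfig(
        canvas=256, n_benign=3, n_small_malignant=5, n_single_cell=6,
        benign_radius=(20.0, 30.0), malignant_radius=(7.0, 12.0),
        n_artefacts=n_artefacts,
    )


def _artefact_regions(scene: synthetic.SyntheticScene) -> list[maskgen.Region]:
    """Correction annotations covering the scene's artefact blobs (the toy
    analogue of non-experts outlining stained debris)."""
    regions = []
    theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    for a in scene.artefacts:
        rad = a.radius + 1.5
        poly = np.stack([a.centre[0] + rad * np.sin(theta),
                         a.centre[1] + rad * np.cos(theta)], axis=1)
        regions.append(maskgen.Region(polygon=poly, label="artefact"))
    return regions


def labelled_he_tile(
    scene_seed: int,
    n_artefacts: int = 0,
    correct_artefacts: bool = False,
    max_displacement: float = 2.0,
    config: synthetic.SceneConfig | None = None,
):
    """One training tile: deformed H&E image plus its IHC-pipeline labels
    carried into the H&E frame.

    Returns ``(he_image, labels, truth_mask)``.  The labels come from the
    deconvolution-threshold-morphology pipeline on the IHC rendering
    (optionally with artefact-region corrections applied), warped into the
    deformed H&E frame with the generating field — the synthetic stand-in for
    the registration output.
    """
    cfg = config or toy_scene_config(n_artefacts)
    scene = synthetic.generate_scene(cfg, seed=scene_seed)
    ihc = synthetic.render(scene, "IHC")
    conc = stains.deconvolve(ihc.image, ihc.stains)
    labels = maskgen.ihc_reference_mask(conc)
    if correct_artefacts and scene.artefacts:
        labels, _ = maskgen.apply_corrections(labels, _artefact_regions(scene))
    he = synthetic.render(scene, "HE")
    warped_he, field = synthetic.deform_pair(he, max_displacement, smoothness=20.0,
                                             seed=scene_seed + 7919)
    warped_labels = registration.warp(labels, field, "nearest")
    return warped_he.image, warped_labels, warped_he.truth_mask


def _patch_set(tiles, per_tile: int, patch_size: int, rng) -> list[training.PatchSample]:
    scfg = training.SamplerConfig(mode="uniform_over_classes", patch_size=patch_size)
    out = []
    for i, (img, lab, _) in enumerate(tiles):
        out += [training.sample_patch(img, lab, scfg, rng, slide_id=str(i))
                for _ in range(per_tile)]
    return out


def _heldout_f1(model, seeds, n_artefacts=0, tile=128, halo=16):
    """Pooled F1 over held-out tiles (undeformed H&E vs geometric truth)."""
    counts = np.zeros(4, dtype=np.int64)
    per_tile = []
    for s in seeds:
        scene = synthetic.generate_scene(toy_scene_config(n_artefacts), seed=s)
        he = synthetic.render(scene, "HE")
        pred = unet.argmax_mask(unet.predict_tiled(model, he.image, tile_size=tile, halo=halo))
        m = evaluate.confusion(pred, he.truth_mask)
        counts += (m.tp, m.fp, m.fn, m.tn)
        per_tile.append(m.f1)
    pooled = evaluate.SegmentationMetrics(*map(int, counts))
    return pooled.f1, per_tile


@dataclass
class ToyResult:
    heldout_f1: float
    per_tile_f1: list
    history: "object"  # pandas DataFrame
    model: unet.UNet


def two_stage_toy(
    seed: int = 0,
    n_train_tiles: int = 8,
    patches_per_tile: int = 8,
    n_val_tiles: int = 2,
    patch_size: int = 128,
    filters: tuple[int, ...] = (8, 16, 32),
    epochs: int = 35,
    heldout_seeds: tuple[int, ...] = (200, 201, 202),
) -> ToyResult:
    """Train a small H&E U-Net on IHC-pipeline labels and score held-out tiles.

    The defaults (64 patches of 128 x 128, depth-3 net with 8 base filters,
    35 epochs) run in a few minutes on one CPU.
    """
    rng = np.random.default_rng(seed)
    train_tiles = [labelled_he_tile(seed * 1000 + i) for i in range(n_train_tiles)]
    val_tiles = [labelled_he_tile(seed * 1000 + 500 + i) for i in range(n_val_tiles)]
    train_patches = _patch_set(train_tiles, patches_per_tile, patch_size, rng)
    val_patches = _patch_set(val_tiles, patches_per_tile, patch_size, rng)

    model = unet.build_unet(unet.UNetSpec(filters=filters), seed=seed + 7)
    sched = training.TrainingSchedule(max_epochs=epochs, plateau_patience=10, seed=seed + 3)
    hist = training.train(model, train_patches, val_patches, sched,
                          augment_config=training.AugmentConfig())
    pooled, per_tile = _heldout_f1(model, heldout_seeds)
    return ToyResult(heldout_f1=pooled, per_tile_f1=per_tile, history=hist, model=model)


def corrected_vs_corrupted(
    seed: int = 0,
    n_repeats: int = 3,
    n_train_tiles: int = 4,
    patches_per_tile: int = 6,
    patch_size: int = 96,
    filters: tuple[int, ...] = (8, 16, 32),
    epochs: int = 10,
    n_artefacts: int = 6,
) -> list[tuple[float, float]]:
    """Artefact-corrupted versus corrected supervision, otherwise identical.

    For each repeat, two nets are trained from the same initialisation and
    patch locations: one on raw deconvolution labels of artefact-laden scenes
    (debris blobs labelled epithelium), one on labels with the artefact
    regions corrected to background.  Held-out tiles also contain artefacts,
    so the corrupted net's false positives on debris depress its F1.  Returns
    ``[(corrected_f1, corrupted_f1), ...]`` per repeat.
    """
    out = []
    for rep in range(n_repeats):
        base = seed * 100 + rep * 17
        results = {}
        for corrected in (True, False):
            rng = np.random.default_rng(base + 1)  # same draws for both arms
            tiles = [labelled_he_tile(base * 50 + i, n_artefacts=n_artefacts,
                                      correct_artefacts=corrected)
                     for i in range(n_train_tiles)]
            val = [labelled_he_tile(base * 50 + 300 + i, n_artefacts=n_artefacts,
                                    correct_artefacts=corrected)
                   for i in range(1)]
            train_patches = _patch_set(tiles, patches_per_tile, patch_size, rng)
            val_patches = _patch_set(val, patches_per_tile, patch_size, rng)
            model = unet.build_unet(unet.UNetSpec(filters=filters), seed=base + 7)
            sched = training.TrainingSchedule(max_epochs=epochs, plateau_patience=8,
                                              seed=base + 3)
            training.train(model, train_patches, val_patches, sched,
                           augment_config=training.AugmentConfig())
            pooled, _ = _heldout_f1(model, (base + 900, base + 901),
                                    n_artefacts=n_artefacts, tile=96, halo=16)
            results[corrected] = pooled
        out.append((results[True], results[False]))
    return out
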