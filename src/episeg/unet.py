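"""Modified U-Net architectures for epithelium segmentation.

Two variants mirror the two pipeline stages: a five-level net for segmenting
epithelium in deconvolved IHC, and a six-level net for H&E (the extra level
enlarges the receptive field, which helps reject corpora-amylacea-like debris;
its per-level filter counts are lowered so the deeper net has *fewer*
parameters overall).  Both deviate from the original U-Net in the same ways:

* additive (residual) shortcut inside every two-convolution block, projected
  with a 1x1 convolution when the channel counts differ;
* interpolation-based up-sampling (bilinear x2 followed by a 3x3 convolution)
  in the expansion path instead of transposed convolution;
* "same"-padded convolutions, so the output mask has the input's shape.

Inference on images larger than memory allows goes through overlapping tiles
with a cropped halo; class probabilities come from a per-pixel softmax, and
the binary mask is the argmax with ties resolved to background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "UNetSpec",
    "IHC_SPEC",
    "HE_SPEC",
    "UNet",
    "build_unet",
    "predict_tiled",
    "argmax_mask",
]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture description.

    ``filters`` holds the convolution width per level, shallow to deep; its
    length is the depth.  The input patch side must be divisible by
    ``2**(depth - 1)``.
    """

    filters: tuple[int, ...] = (32, 64, 128, 256, 512)
    in_channels: int = 3
    out_classes: int = 2
    intra_block_skips: bool = True

    def __post_init__(self):
        if len(self.filters) < 2:
            raise ValueError("need at least 2 levels")
        if self.out_classes != 2:
            raise ValueError("binary segmentation: out_classes must be 2")

    @property
    def depth(self) -> int:
        return len(self.filters)

    def check_input_size(self, h: int, w: int) -> None:
        d = 2 ** (self.depth - 1)
        if h % d or w % d:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2**(depth-1) = {d}"
            )


#: five-level net trained on IHC
IHC_SPEC = UNetSpec(filters=(32, 64, 128, 256, 512))
#: six-level net trained on H&E; filter counts are lowered at every level so
#: the deeper net still has fewer parameters than the five-level one
HE_SPEC = UNetSpec(filters=(16, 32, 64, 128, 256, 384))


class _ConvBlock:
    """conv-bn-relu, conv-bn, additive shortcut, relu."""

    def __init__(self, in_ch, out_ch, rng, residual=True):
        self.c1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.n1 = nn.BatchNorm2d(out_ch)
        self.r1 = nn.ReLU()
        self.c2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.n2 = nn.BatchNorm2d(out_ch)
        self.r2 = nn.ReLU()
        self.residual = residual
        self.proj = nn.Conv2d(in_ch, out_ch, 1, rng) if (residual and in_ch != out_ch) else None

    def layers(self):
        out = [self.c1, self.n1, self.c2, self.n2]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x, train=True):
        y = self.r1.forward(self.n1.forward(self.c1.forward(x, train), train), train)
        y = self.n2.forward(self.c2.forward(y, train), train)
        if self.residual:
            y = y + (x if self.proj is None else self.proj.forward(x, train))
        return self.r2.forward(y, train)

    def backward(self, dy):
        dy = self.r2.backward(dy)
        dx_short = dy
        d = self.c2.backward(self.n2.backward(dy))
        d = self.c1.backward(self.n1.backward(self.r1.backward(d)))
        if self.residual:
            d = d + (dx_short if self.proj is None else self.proj.backward(dx_short))
        return d


class _UpBlock:
    """bilinear x2 -> 3x3 conv -> concat skip -> conv block."""

    def __init__(self, in_ch, skip_ch, out_ch, rng, residual=True):
        self.up = nn.Upsample2xBilinear()
        self.reduce = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.block = _ConvBlock(out_ch + skip_ch, out_ch, rng, residual)
        self.skip_ch = skip_ch

    def layers(self):
        return [self.reduce] + self.block.layers()

    def forward(self, x, skip, train=True):
        y = self.reduce.forward(self.up.forward(x, train), train)
        return self.block.forward(np.concatenate([skip, y], axis=1), train)

    def backward(self, dy):
        d = self.block.backward(dy)
        dskip, dred = d[:, : self.skip_ch], d[:, self.skip_ch:]
        return self.up.backward(self.reduce.backward(dred)), dskip


class UNet:
    """Encoder-decoder with long skip connections; built by :func:`build_unet`."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        res = spec.intra_block_skips
        f = spec.filters
        self.enc = [_ConvBlock(spec.in_channels, f[0], rng, res)]
        self.pools = []
        for lvl in range(1, spec.depth):
            self.pools.append(nn.MaxPool2x2())
            self.enc.append(_ConvBlock(f[lvl - 1], f[lvl], rng, res))
        self.dec = []
        for lvl in range(spec.depth - 2, -1, -1):
            self.dec.append(_UpBlock(f[lvl + 1], f[lvl], f[lvl], rng, res))
        self.head = nn.Conv2d(f[0], spec.out_classes, 1, rng)

    # -- plumbing -----------------------------------------------------------
    def _layers(self):
        out = []
        for b in self.enc:
            out.extend(b.layers())
        for u in self.dec:
            out.extend(u.layers())
        out.append(self.head)
        return out

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def parameter_count(self) -> int:
        return sum(p.size for p, _ in self.params())

    def get_state(self):
        state = [p.copy() for p, _ in self.params()]
        state += [(bn.run_mean.copy(), bn.run_var.copy())
                  for bn in self._layers() if isinstance(bn, nn.BatchNorm2d)]
        return state

    def set_state(self, state):
        params = self.params()
        for (p, _), saved in zip(params, state[: len(params)]):
            p[...] = saved
        bns = [b for b in self._layers() if isinstance(b, nn.BatchNorm2d)]
        for bn, (rm, rv) in zip(bns, state[len(params):]):
            bn.run_mean[...] = rm
            bn.run_var[...] = rv

    # -- compute ------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits of shape (N, 2, H, W) for input (N, 3, H, W)."""
        self.spec.check_input_size(x.shape[2], x.shape[3])
        x = x.astype(np.float32)
        skips = []
        y = self.enc[0].forward(x, train)
        for pool, block in zip(self.pools, self.enc[1:]):
            skips.append(y)
            y = block.forward(pool.forward(y, train), train)
        for up, skip in zip(self.dec, reversed(skips)):
            y = up.forward(y, skip, train)
        return self.head.forward(y, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up in reversed(self.dec):
            d, dskip = up.backward(d)
            dskips.append(dskip)
        # dskips[i] belongs to encoder level i (backward ran shallowest-first)
        for i in range(len(self.enc) - 1, 0, -1):
            d = self.pools[i - 1].backward(self.enc[i].backward(d))
            d = d + dskips[i - 1]
        self.enc[0].backward(d)

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Class probabilities (H, W, 2) for an (H, W, 3) image in [0, 1]."""
        x = np.ascontiguousarray(image.transpose(2, 0, 1))[None]
        logits = self.forward(x, train=False)
        return nn.softmax(logits)[0].transpose(1, 2, 0)


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet:
    """Instantiate a U-Net with deterministic He initialisation under ``seed``."""
    return UNet(spec, seed)


def predict_tiled(
    model: UNet, image: np.ndarray, tile_size: int = 512, halo: int = 32
) -> np.ndarray:
    """Whole-image inference by overlapping tiles with halo cropping.

    Tiles of ``tile_size`` (with a ``halo``-wide context margin discarded
    after the forward pass) cover the image; edges are mirror-padded so every
    pixel sits in some tile interior.  Returns (H, W, 2) probabilities.  An
    image that fits one tile is processed in a single forward pass.
    """
    h, w = image.shape[:2]
    div = 2 ** (model.spec.depth - 1)
    if tile_size % div or tile_size <= 0:
        raise ValueError(f"tile_size must be a positive multiple of {div}")
    if h <= tile_size and w <= tile_size and h % div == 0 and w % div == 0:
        return model.predict_probs(image)
    if halo % div:
        raise ValueError(f"halo must be divisible by {div}")

    core = tile_size - 2 * halo
    if core <= 0:
        raise ValueError("halo too large for tile size")
    padded = np.pad(image, ((halo, halo + (-h) % core), (halo, halo + (-w) % core), (0, 0)),
                    mode="reflect")
    out = np.zeros((h + (-h) % core, w + (-w) % core, 2), dtype=np.float32)
    for r0 in range(0, h, core):
        for c0 in range(0, w, core):
            tile = padded[r0:r0 + tile_size, c0:c0 + tile_size]
            probs = model.predict_probs(tile)
            out[r0:r0 + core, c0:c0 + core] = probs[halo:halo + core, halo:halo + core]
    return out[:h, :w]


def argmax_mask(probs: np.ndarray) -> np.ndarray:
    """Binary epithelium mask from (H, W, 2) probabilities; exact ties go to
    background."""
    return probs[..., 1] > probs[..., 0]
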