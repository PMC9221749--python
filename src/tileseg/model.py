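"""Compact U-Net-style encoder-decoder for 4-channel multi-label output.

The encoder halves resolution ``depth`` times while doubling width; the
symmetric decoder upsamples and fuses the matching encoder feature maps
through skip connections.  The head is a 1x1 convolution with a per-channel
logistic (sigmoid) — channels are independent probabilities, NOT a softmax,
because mask channels may overlap.

Implemented on the NumPy layer kit in :mod:`tileseg.nn`; weights are
seed-deterministic and checkpoints are ``.npz`` archives with the config and
intensity normalizer embedded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from skimage.transform import resize

from tileseg.channels import N_CLASSES
from tileseg.nn import Adam, Conv2d, InstanceNorm, MaxPool2, Param, ReLU, Upsample2

__all__ = ["ModelConfig", "Normalizer", "UNet", "build_model", "predict_tiles",
           "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size`` is the square working resolution tiles are resampled to;
    ``depth`` is the number of encoder (downsampling) levels; ``base_width``
    the channel count at the first level.
    """

    input_size: int = 64
    depth: int = 3
    base_width: int = 8
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes is fixed at {N_CLASSES}")
        if self.depth < 1 or self.base_width < 1:
            raise ValueError("depth and base_width must be >= 1")
        if self.input_size % (1 << self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {1 << self.depth}"
            )


@dataclass(frozen=True)
class Normalizer:
    """Intensity standardization fitted on the training split only."""

    mean: float = 0.0
    sd: float = 1.0

    def __call__(self, x01: np.ndarray) -> np.ndarray:
        return (x01 - self.mean) / max(self.sd, 1e-8)


class _ConvBlock:
    """(conv3x3 -> instance norm -> ReLU) x2."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.n1 = InstanceNorm(out_ch)
        self.r1 = ReLU()
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)
        self.n2 = InstanceNorm(out_ch)
        self.r2 = ReLU()

    def params(self) -> list[Param]:
        return (self.c1.params() + self.n1.params()
                + self.c2.params() + self.n2.params())

    def forward(self, x):
        x = self.r1.forward(self.n1.forward(self.c1.forward(x)))
        return self.r2.forward(self.n2.forward(self.c2.forward(x)))

    def backward(self, d):
        d = self.c2.backward(self.n2.backward(self.r2.backward(d)))
        return self.c1.backward(self.n1.backward(self.r1.backward(d)))


class UNet:
    """U-Net with ``depth`` encoder levels and a symmetric decoder.

    Maps a 1-channel square image batch ``(N, 1, S, S)`` to independent
    per-channel probabilities ``(N, 4, S, S)``.
    """

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.normalizer: Normalizer = Normalizer()
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        d, w = config.depth, config.base_width

        self.enc = [_ConvBlock(1 if i == 0 else w << (i - 1), w << i, rng) for i in range(d)]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = _ConvBlock(w << (d - 1), w << d, rng)
        self.ups = [Upsample2() for _ in range(d)]
        # per decoder level i (deepest first): channel-reducing conv, then fuse block
        self.reduce = [Conv2d((w << (i + 1)), w << i, 3, rng) for i in reversed(range(d))]
        self.reduce_relu = [ReLU() for _ in range(d)]
        self.dec = [_ConvBlock((w << i) * 2, w << i, rng) for i in reversed(range(d))]
        self.head = Conv2d(w, config.n_classes, 1, rng)
        # background prior: start channels near p~0.12 so sparse-foreground
        # dice training neither saturates nor wastes epochs un-learning an
        # all-positive start
        self.head.b.value[...] = -2.0

    # -- parameters ------------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.enc:
            out += blk.params()
        out += self.bottleneck.params()
        for conv in self.reduce:
            out += conv.params()
        for blk in self.dec:
            out += blk.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
        if x.shape[2] % (1 << self.config.depth) or x.shape[3] % (1 << self.config.depth):
            raise ValueError(
                f"spatial extent {x.shape[2:]} not divisible by 2^depth"
            )
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # layers run channels-last
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for up, red, rrelu, blk, skip in zip(
            self.ups, self.reduce, self.reduce_relu, self.dec, reversed(skips)
        ):
            x = rrelu.forward(red.forward(up.forward(x)))
            self._skip_ch.append(skip.shape[-1])
            x = blk.forward(np.concatenate([skip, x], axis=-1))
        logits = self.head.forward(x)
        self._probs = expit(logits)
        return np.ascontiguousarray(self._probs.transpose(0, 3, 1, 2))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate dL/dprobs ((N, 4, H, W)) from the last forward call."""
        dprobs = np.ascontiguousarray(dprobs.transpose(0, 2, 3, 1))
        dlogits = (dprobs * self._probs * (1.0 - self._probs)).astype(np.float32)
        d = self.head.backward(dlogits)
        dskips = []
        for blk, rrelu, red, up, ch in zip(
            reversed(self.dec),
            reversed(self.reduce_relu),
            reversed(self.reduce),
            reversed(self.ups),
            reversed(self._skip_ch),
        ):
            d = blk.backward(d)
            dskips.append(np.ascontiguousarray(d[..., :ch]))
            d = up.backward(red.backward(rrelu.backward(np.ascontiguousarray(d[..., ch:]))))
        dskips.reverse()  # now deepest-last -> shallowest-first order fix below
        d = self.bottleneck.backward(d)
        # dskips[k] pairs with decoder level k (deepest first); encoder order is
        # shallow first, so walk encoders in reverse.
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), dskips):
            d = pool.backward(d)
            d = blk.backward(d + dskip)

    # -- weights I/O -----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match architecture")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("checkpoint tensor shape mismatch")
            p.value[...] = a


def build_model(config: ModelConfig, seed: int) -> UNet:
    """Construct a seed-deterministic U-Net for the given config."""
    return UNet(config, seed)


def make_optimizer(model: UNet, lr: float, beta1: float = 0.9) -> Adam:
    return Adam(model.params(), lr=lr, beta1=beta1)


def _to_unit_interval(tile: np.ndarray) -> np.ndarray:
    tile = np.asarray(tile)
    if tile.dtype == np.uint8 or np.issubdtype(tile.dtype, np.integer):
        return tile.astype(np.float32) / 255.0
    return tile.astype(np.float32)


def predict_tiles(model, tiles: Sequence[np.ndarray], input_size: int | None = None):
    """Run a tile predictor over crops of arbitrary (per-tile) sizes.

    Each tile is scaled to [0, 1], standardized with the model's fitted
    normalizer, resampled bilinearly to the model's square working resolution
    (skipped when the tile already has that shape), passed through the model,
    and the 4-channel probability map is resampled bilinearly back to the
    tile's native size.  Output order matches input order.

    ``model`` must be callable on a ``(N, 1, s, s)`` batch returning
    ``(N, 4, s, s)`` probabilities.  A model whose working resolution is
    ``None`` (duck-typed via ``model.config.input_size``) is applied at each
    tile's native resolution with no resampling or normalization — used for
    oracle predictors in validation.
    """
    if len(tiles) == 0:
        raise ValueError("empty tile list")
    if input_size is None:
        cfg = getattr(model, "config", None)
        input_size = getattr(cfg, "input_size", None) if cfg is not None else None

    if input_size is None:
        return [model(t[None, None].astype(np.float32))[0] for t in tiles]

    normalizer = getattr(model, "normalizer", None) or Normalizer()
    batch = np.empty((len(tiles), 1, input_size, input_size), dtype=np.float32)
    for k, tile in enumerate(tiles):
        x = normalizer(_to_unit_interval(tile))
        if x.shape != (input_size, input_size):
            x = resize(x, (input_size, input_size), order=1, preserve_range=True,
                       anti_aliasing=False)
        batch[k, 0] = x
    probs = model(batch)
    out = []
    for k, tile in enumerate(tiles):
        p = probs[k]
        if tile.shape != (input_size, input_size):
            p = np.stack(
                [
                    resize(p[c], tile.shape, order=1, preserve_range=True,
                           anti_aliasing=False)
                    for c in range(p.shape[0])
                ]
            )
            p = np.clip(p, 0.0, 1.0)
        out.append(p.astype(np.float32))
    return out


def save_model(model: UNet, path) -> None:
    """Write weights + config + normalizer as a ``.npz`` checkpoint."""
    path = Path(path)
    meta = {"config": asdict(model.config),
            "normalizer": asdict(model.normalizer)}
    arrays = {f"param_{i:03d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> UNet:
    with np.load(Path(path)) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        names = sorted(k for k in zf.files if k.startswith("param_"))
        arrays = [zf[k] for k in names]
    model = UNet(ModelConfig(**meta["config"]), seed=0)
    model.load_state_arrays(arrays)
    model.normalizer = Normalizer(**meta["normalizer"])
    return model
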