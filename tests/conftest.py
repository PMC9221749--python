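import numpy as np
import pytest

from tileseg.synthetic import GenConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """12 tiny scenes with elevated class probabilities (fast, reused)."""
    cfg = GenConfig.scaled_default(
        64, 128, n_teeth=10, p_filling=0.8, p_crown=0.6, p_root_canal=0.5,
        p_implant=0.3, seed=11,
    )
    images, _ = generate_dataset(cfg, 12, seed=11)
    return images


def bit_encode(mask: np.ndarray) -> np.ndarray:
    """Encode a (4, H, W) boolean mask into a uint8 image, one bit per channel."""
    out = np.zeros(mask.shape[1:], dtype=np.uint8)
    for c in range(mask.shape[0]):
        out |= mask[c].astype(np.uint8) << c
    return out


class BitOracleModel:
    """Perfect predictor for bit-encoded images.

    Has no ``config`` attribute, so the prediction path applies it at each
    tile's native resolution with no resampling or normalization.
    """

    def __call__(self, x: np.ndarray) -> np.ndarray:
        vals = np.rint(x[:, 0]).astype(np.int64)
        return np.stack([(vals >> c) & 1 for c in range(4)], axis=1).astype(np.float32)


class ConstantModel:
    """Outputs a fixed probability everywhere; native resolution."""

    def __init__(self, value: float):
        self.value = value

    def __call__(self, x: np.ndarray) -> np.ndarray:
        n, _, h, w = x.shape
        return np.full((n, 4, h, w), self.value, dtype=np.float32)
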