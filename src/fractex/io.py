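"""Image readers/writers and run configuration.

Images are exchanged as PNG/TIFF/PGM/PPM (8- or 16-bit) and held in memory as
float arrays in [0, 1], 2-D for grey and (H, W, 3) for colour.  A
:class:`RunConfig` mirrors every knob of the pipeline and round-trips through
YAML losslessly, with defaults reproducing the reference settings (5x5 mask,
alpha = 1, beta = 1.7, Gaussian input noise of variance 0.01).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .adaptive import AdaptiveParams
from .enhance import EnhanceConfig

__all__ = ["read_image", "write_image", "RunConfig"]


def read_image(path) -> np.ndarray:
    """Read an image file to float intensities in [0, 1].

    Integer data is scaled by its dtype range (255 or 65535); float data is
    clipped to [0, 1].  An alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input image not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim not in (2, 3):
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / float(info.max)
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_image(path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write float intensities in [0, 1] as an 8- or 16-bit image file."""
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(image * 255.0).astype(np.uint8)
    else:
        data = np.round(image * 65535.0).astype(np.uint16)
    iio.imwrite(Path(path), data)


@dataclass
class RunConfig:
    """Flat, serializable view of every pipeline setting."""

    # enhancement
    m: int = 2
    mode: str = "vofcd"
    fixed_v: float = 0.5
    colour_mode: str = "hsi"
    border: str = "replicate"
    clip: str = "clip"
    order_quantum: float = 0.001
    # adaptive order
    alpha: float = 1.0
    beta: float = 1.7
    threshold: float = 0.01
    window: int = 5
    bins: int = 256
    gradient_op: str = "central"
    clamp: bool = True
    k1: float = 0.45
    k2: float = 0.01
    k3: float = 0.54
    # metrics
    metric_bins: int = 256
    madc_variant: str = "literal"
    noise_region_frac: float = 0.1
    # misc
    seed: int = 0
    bit_depth: int = 8

    _ADAPTIVE_KEYS = (
        "alpha", "beta", "threshold", "window", "bins",
        "gradient_op", "clamp", "k1", "k2", "k3",
    )
    _ENHANCE_KEYS = (
        "m", "mode", "fixed_v", "colour_mode", "border", "clip", "order_quantum",
    )

    def adaptive_params(self) -> AdaptiveParams:
        return AdaptiveParams(**{k: getattr(self, k) for k in self._ADAPTIVE_KEYS})

    def enhance_config(self) -> EnhanceConfig:
        cfg = EnhanceConfig(
            **{k: getattr(self, k) for k in self._ENHANCE_KEYS},
            adaptive=self.adaptive_params(),
        )
        return cfg.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def merged(self, overrides: dict) -> "RunConfig":
        """New config with non-None override values applied (CLI wins)."""
        data = self.to_dict()
        for key, value in overrides.items():
            if value is not None:
                if key not in data:
                    raise ValueError(f"unknown config key {key!r}")
                data[key] = value
        return RunConfig.from_dict(data)
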