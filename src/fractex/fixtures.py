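"""Seeded synthetic images with controllable texture and noise structure.

The clinical MRI slices this kind of enhancement targets are not
redistributable, so every stage of the pipeline is exercised on generated
stand-ins: flat patches (fixed-point checks), ramps (exact gradients),
checkerboards and band-limited sinusoids (rich texture), smooth blobs on a
dark background (edges plus an MRI-like background for SNR regions), step
edges (margin detection) and isolated impulses (noise-like pixels).  Additive
Gaussian noise with mean 0 and variance 0.01 matches the noise the enhancement
algorithm takes as its input condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FixtureSpec", "FIXTURE_KINDS", "make_fixture", "add_gaussian_noise"]

FIXTURE_KINDS = (
    "constant",
    "ramp",
    "checkerboard",
    "sinusoid",
    "blobs",
    "step-edge",
    "impulse",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic image; identical spec + seed -> identical image.

    kind-specific parameters: ``level`` (constant/base intensity), ``slope``
    (ramp increment per pixel; None means full-range 0..1), ``period`` (pixels
    per checkerboard cell / sinusoid cycle), ``amplitude`` (sinusoid half
    swing around 0.5), ``count`` (number of blobs or impulses), ``height``
    (blob/step/impulse amplitude above the base level).
    """

    kind: str
    size: tuple[int, int] = (64, 64)
    seed: int = 0
    level: float = 0.5
    slope: float | None = None
    period: int = 8
    amplitude: float = 0.4
    count: int = 5
    height: float = 0.4


def make_fixture(spec: FixtureSpec) -> np.ndarray:
    """Deterministic image in [0, 1] for the given spec."""
    if spec.kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; expected one of {FIXTURE_KINDS}")
    H, W = spec.size
    if H < 8 or W < 8:
        raise ValueError(f"fixture size must be at least 8x8, got {spec.size}")
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    if spec.kind == "constant":
        img = np.full((H, W), spec.level)
    elif spec.kind == "ramp":
        slope = spec.slope if spec.slope is not None else 1.0 / (W - 1)
        img = xx * slope
    elif spec.kind == "checkerboard":
        img = (((yy // spec.period) + (xx // spec.period)) % 2).astype(float)
    elif spec.kind == "sinusoid":
        img = spec.level + spec.amplitude * np.sin(2 * np.pi * xx / spec.period) * np.sin(
            2 * np.pi * yy / spec.period
        )
    elif spec.kind == "blobs":
        img = np.full((H, W), 0.05)
        sigma = max(2.0, min(H, W) / 12.0)
        centres = rng.uniform([0.15 * H, 0.15 * W], [0.85 * H, 0.85 * W], size=(spec.count, 2))
        for cy, cx in centres:
            img += spec.height * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    elif spec.kind == "step-edge":
        img = np.where(xx < W / 2, spec.level, spec.level + spec.height)
    elif spec.kind == "impulse":
        img = np.full((H, W), spec.level)
        idx = rng.choice(H * W, size=spec.count, replace=False)
        img.ravel()[idx] += spec.height
    return np.clip(img, 0.0, 1.0)


def add_gaussian_noise(
    image: np.ndarray,
    mean: float = 0.0,
    var: float = 0.01,
    seed: int | None = None,
    clip: bool = True,
) -> np.ndarray:
    """Add i.i.d. Gaussian noise N(mean, var) per pixel.

    Intensities are clipped back to [0, 1] unless ``clip`` is disabled (the
    unclipped form is what statistical checks of the noise moments use).
    """
    if var < 0:
        raise ValueError(f"variance must be >= 0, got {var}")
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    noisy = image + rng.normal(mean, np.sqrt(var), size=image.shape)
    return np.clip(noisy, 0.0, 1.0) if clip else noisy
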