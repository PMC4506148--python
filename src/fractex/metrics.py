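"""Image quality measures and the constrained weight grid search.

SNR is the squared ratio of RMS amplitudes between a signal region and a
background (noise) region; Ent is the Shannon entropy of the global intensity
histogram in bits; STD the population standard deviation of the intensities;
MADC a clarity/activity measure built from horizontal and vertical
nearest-neighbour differences.  The weight search sweeps the convex weights
(k1, k2, k3) of the adaptive order's composite feature over the 0.01-step
simplex (floor 0.01 per weight, 4851 triples) and records all four measures of
the enhanced image for every triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptive import (
    AdaptiveParams,
    composite_feature,
    gradient_field,
    local_entropy_field,
    local_roughness_field,
    minmax_normalize,
    noise_margin_indicator,
    order_field,
)
from .enhance import EnhanceConfig, _apply_order_field, _finalize

__all__ = [
    "QualityReport",
    "WeightSearchResult",
    "snr",
    "corner_background_masks",
    "global_entropy",
    "intensity_std",
    "madc",
    "quality_report",
    "weight_grid_search",
    "METRIC_NAMES",
]

METRIC_NAMES = ("snr", "ent", "std", "madc")


@dataclass
class QualityReport:
    """The four quality measures of one image, plus the regions used for SNR."""

    snr: float | None
    ent: float
    std: float
    madc: float
    a_signal: float | None = None
    a_noise: float | None = None
    signal_mask: np.ndarray | None = None
    noise_mask: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "snr": self.snr,
            "ent": self.ent,
            "std": self.std,
            "madc": self.madc,
            "a_signal": self.a_signal,
            "a_noise": self.a_noise,
        }


@dataclass
class WeightSearchResult:
    """Best/worst weight triples per metric and the full grid table."""

    best: dict
    worst: dict
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        return {"best": self.best, "worst": self.worst, "n_triples": int(len(self.table))}


def _rms(values: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(values, dtype=float))))


def snr(image: np.ndarray, signal_mask: np.ndarray, noise_mask: np.ndarray) -> float:
    """(RMS over the signal region / RMS over the noise region) squared."""
    image = np.asarray(image, dtype=float)
    signal_mask = np.asarray(signal_mask, dtype=bool)
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if not signal_mask.any() or not noise_mask.any():
        raise ValueError("signal and noise masks must both be non-empty")
    if (signal_mask & noise_mask).any():
        raise ValueError("signal and noise masks must be disjoint")
    a_noise = _rms(image[noise_mask])
    if a_noise == 0.0:
        raise ZeroDivisionError("noise region has zero RMS amplitude; SNR undefined")
    return (_rms(image[signal_mask]) / a_noise) ** 2


def corner_background_masks(
    shape: tuple[int, int], frac: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Default signal/noise regions for images without an explicit background.

    The noise region is the union of four corner blocks, each ``frac`` of the
    image side (a background proxy for brain MRI, where the corners lie
    outside the head); the signal region is the complement.
    """
    H, W = shape[:2]
    bh, bw = max(1, int(round(frac * H))), max(1, int(round(frac * W)))
    noise = np.zeros((H, W), dtype=bool)
    noise[:bh, :bw] = noise[:bh, -bw:] = noise[-bh:, :bw] = noise[-bh:, -bw:] = True
    return ~noise, noise


def global_entropy(image: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the whole-image intensity histogram on [0, 1]."""
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    image = np.asarray(image, dtype=float)
    counts, _ = np.histogram(np.clip(image.ravel(), 0.0, 1.0), bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / image.size
    return float(-(p * np.log2(p)).sum())


def intensity_std(image: np.ndarray) -> float:
    """Population standard deviation of all pixel intensities."""
    return float(np.std(np.asarray(image, dtype=float)))


def madc(image: np.ndarray, variant: str = "literal") -> float:
    """Mean absolute difference coefficient over rows and columns.

    With Ix = (s(x,y) - s(x-1,y))^2 and Iy the column analogue (replicate
    padding for the first row/column), the "literal" variant averages
    Ix^2 + Iy^2 (fourth powers of the differences, the formula as printed) and
    the "squared-diff" variant averages Ix + Iy (plain squared differences,
    provided because the inner squaring reads like a typo).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ValueError(f"expected a 2-D image at least 2x2, got shape {image.shape}")
    dx = np.diff(image, axis=0, prepend=image[:1, :])
    dy = np.diff(image, axis=1, prepend=image[:, :1])
    Ix, Iy = dx * dx, dy * dy
    if variant == "literal":
        return float(np.mean(Ix * Ix + Iy * Iy))
    if variant == "squared-diff":
        return float(np.mean(Ix + Iy))
    raise ValueError(f"unknown MADC variant {variant!r}")


def quality_report(
    image: np.ndarray,
    signal_mask: np.ndarray | None = None,
    noise_mask: np.ndarray | None = None,
    bins: int = 256,
    madc_variant: str = "literal",
) -> QualityReport:
    """All four measures of one grey image with the default corner background."""
    image = np.asarray(image, dtype=float)
    if signal_mask is None or noise_mask is None:
        signal_mask, noise_mask = corner_background_masks(image.shape)
    a_noise = _rms(image[np.asarray(noise_mask, bool)])
    a_signal = _rms(image[np.asarray(signal_mask, bool)])
    value = snr(image, signal_mask, noise_mask) if a_noise > 0 else None
    return QualityReport(
        snr=value,
        ent=global_entropy(image, bins=bins),
        std=intensity_std(image),
        madc=madc(image, variant=madc_variant),
        a_signal=a_signal,
        a_noise=a_noise if a_noise > 0 else None,
        signal_mask=np.asarray(signal_mask, bool),
        noise_mask=np.asarray(noise_mask, bool),
    )


def simplex_triples(step: int = 100, floor: int = 1):
    """Integer-hundredth weight triples (a+b+c = step, each >= floor), in
    lexicographic order of (k1, k2)."""
    for a in range(floor, step - 2 * floor + 1):
        for b in range(floor, step - a - floor + 1):
            yield a / step, b / step, (step - a - b) / step


def weight_grid_search(
    image: np.ndarray,
    cfg: EnhanceConfig | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
    signal_mask: np.ndarray | None = None,
    noise_mask: np.ndarray | None = None,
    bins: int = 256,
    madc_variant: str = "literal",
) -> WeightSearchResult:
    """Sweep (k1, k2, k3) over the 0.01-step simplex and score each enhancement.

    The feature fields (gradient, entropy, roughness, indicator) depend only on
    the image and are computed once; each of the 4851 triples then forms its
    composite feature, order field and enhanced image, and the requested
    metrics are recorded.  Ties in the per-metric extremes are broken toward
    the lexicographically smallest (k1, k2).
    """
    cfg = (cfg or EnhanceConfig()).validate()
    if cfg.mode != "vofcd":
        raise ValueError("the weight search varies the adaptive weights; mode must be 'vofcd'")
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    image = np.asarray(image, dtype=float)
    p = cfg.adaptive
    gn = minmax_normalize(gradient_field(image, op=p.gradient_op))
    en = minmax_normalize(local_entropy_field(image, window=p.window, bins=p.bins))
    qn = minmax_normalize(local_roughness_field(image, window=p.window)[0])
    R = noise_margin_indicator(gn, p.threshold)
    if "snr" in metrics and (signal_mask is None or noise_mask is None):
        signal_mask, noise_mask = corner_background_masks(image.shape)
    rows = []
    for k1, k2, k3 in simplex_triples():
        g = composite_feature(gn, en, qn, k1, k2, k3)
        of = order_field(g, R, alpha=p.alpha, beta=p.beta, clamp=p.clamp)
        out = _finalize(_apply_order_field(image, of.v, cfg), image, cfg)
        row = {"k1": k1, "k2": k2, "k3": k3}
        if "snr" in metrics:
            row["snr"] = snr(out, signal_mask, noise_mask)
        if "ent" in metrics:
            row["ent"] = global_entropy(out, bins=bins)
        if "std" in metrics:
            row["std"] = intensity_std(out)
        if "madc" in metrics:
            row["madc"] = madc(out, variant=madc_variant)
        rows.append(row)
    table = pd.DataFrame(rows)
    best, worst = {}, {}
    for name in metrics:
        vals = table[name].to_numpy()
        # strict comparisons keep the first (lexicographically smallest) triple
        i_best, i_worst = int(np.argmax(vals)), int(np.argmin(vals))
        for store, i in ((best, i_best), (worst, i_worst)):
            store[name] = {
                "k1": float(table.at[i, "k1"]),
                "k2": float(table.at[i, "k2"]),
                "k3": float(table.at[i, "k3"]),
                "value": float(vals[i]),
            }
    return WeightSearchResult(best=best, worst=worst, table=table)
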