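"""Per-pixel image features and the variable fractional order field.

The enhancement strength at each pixel is a fractional order derived from
three bounded local features — gradient magnitude, local Shannon entropy and
local roughness Q = 1 - 1/(1 + sigma^2) — combined as a convex sum
g = k1*grad + k2*H + k3*Q in [0, 1].  A binary margin/noise indicator R
separates structure from isolated noise: a pixel whose gradient magnitude has
no similar value anywhere in its 8-neighbourhood (minimum absolute difference
above a threshold T) is flagged as noise (R = 1).  The order is then

    v = (-1)^R * max(0, exp(alpha * g) - beta),

so structure pixels get a positive (sharpening) order up to e^alpha - beta and
noise pixels a negative (smoothing) order down to beta - e^alpha; the max(0, .)
clamp keeps the field inside those declared ranges (the raw exponential dips
to 1 - beta at g = 0).  Defaults alpha = 1, beta = 1.7 give v in
[0, e - 1.7] ~ [0, 1.018] at structure and [1.7 - e, 0] at noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AdaptiveParams",
    "FeatureFields",
    "OrderField",
    "gradient_field",
    "noise_margin_indicator",
    "local_entropy_field",
    "local_roughness_field",
    "minmax_normalize",
    "composite_feature",
    "order_field",
    "compute_order_field",
]

_E = float(np.e)


@dataclass
class AdaptiveParams:
    """Tunables of the adaptive order pathway.

    alpha, beta : regularization of the exponential order map (defaults 1, 1.7).
    threshold   : T of the margin/noise test, on the min-max normalized
                  gradient scale.  A continuous margin always has a neighbour
                  whose gradient magnitude differs only by the local curvature
                  (about 0.01 of the normalized range for structure resolved
                  over a few pixels), while independent noise produces
                  neighbour differences an order of magnitude larger, so the
                  default sits just above the curvature scale.
    window      : odd side of the local entropy/roughness window (default 5,
                  matching the 5x5 mask footprint).
    bins        : histogram resolution for the local entropy (256 levels on [0,1]).
    gradient_op : "central" (default) or "sobel".
    clamp       : enforce the declared order ranges (max(0, .) on the magnitude).
    k1, k2, k3  : convex weights of gradient/entropy/roughness in g.
    """

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

    def validate(self) -> "AdaptiveParams":
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 1.0 < self.beta < _E:
            raise ValueError(f"beta must lie in (1, e), got {self.beta}")
        if self.threshold < 0:
            raise ValueError(f"threshold T must be >= 0, got {self.threshold}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.bins < 2:
            raise ValueError(f"bins must be >= 2, got {self.bins}")
        _check_weights(self.k1, self.k2, self.k3)
        return self

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.k1, self.k2, self.k3)


@dataclass
class FeatureFields:
    """Raw and normalized per-pixel features feeding the order field."""

    grad: np.ndarray
    entropy: np.ndarray
    roughness: np.ndarray
    sigma2: np.ndarray
    grad_norm: np.ndarray
    entropy_norm: np.ndarray
    roughness_norm: np.ndarray
    R: np.ndarray
    T: float
    weights: tuple[float, float, float]
    g: np.ndarray


@dataclass
class OrderField:
    """Per-pixel fractional order v with its indicator and feature fields."""

    v: np.ndarray
    R: np.ndarray
    alpha: float = 1.0
    beta: float = 1.7
    clamp_mode: bool = True
    features: FeatureFields | None = None

    @property
    def v_max(self) -> float:
        """Upper end of the structure-pixel range, e^alpha - beta."""
        return float(np.exp(self.alpha) - self.beta)

    def summary(self) -> dict:
        return {
            "v_min": float(self.v.min()),
            "v_mean": float(self.v.mean()),
            "v_max": float(self.v.max()),
            "noise_fraction": float(np.mean(self.R == 1)),
        }


def _check_image(image: np.ndarray, min_side: int = 3) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grey image, got shape {image.shape}")
    if min(image.shape) < min_side:
        raise ValueError(f"image must be at least {min_side}x{min_side}, got {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def _check_weights(k1: float, k2: float, k3: float, tol: float = 1e-9) -> None:
    if min(k1, k2, k3) < 0:
        raise ValueError(f"weights must be non-negative, got {(k1, k2, k3)}")
    if abs(k1 + k2 + k3 - 1.0) > tol:
        raise ValueError(f"weights must sum to 1 (tol {tol:g}), got {(k1, k2, k3)}")


def gradient_field(image: np.ndarray, op: str = "central") -> np.ndarray:
    """Gradient magnitude with replicate borders.

    "central": sqrt(Gx^2 + Gy^2) with Gx, Gy central differences over the
    edge-padded image (exact |slope| for linear ramps in the interior).
    "sobel": the 3x3 Sobel magnitude divided by 8 so a unit ramp again maps
    to 1.
    """
    image = _check_image(image)
    if op == "central":
        p = np.pad(image, 1, mode="edge")
        gx = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
        gy = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    elif op == "sobel":
        gx = ndimage.sobel(image, axis=0, mode="nearest") / 8.0
        gy = ndimage.sobel(image, axis=1, mode="nearest") / 8.0
    else:
        raise ValueError(f"unknown gradient operator {op!r}")
    return np.hypot(gx, gy)


def noise_margin_indicator(grad: np.ndarray, T: float) -> np.ndarray:
    """Binary noise indicator from gradient-magnitude similarity.

    R = 0 where some 8-neighbour has a gradient magnitude within T of the
    pixel's own (an edge/margin continues smoothly); R = 1 where no neighbour
    is similar (isolated, noise-like).  Borders use replicate padding.
    """
    grad = _check_image(grad)
    if T < 0:
        raise ValueError(f"threshold T must be >= 0, got {T}")
    p = np.pad(grad, 1, mode="edge")
    min_diff = np.full(grad.shape, np.inf)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nb = p[1 + di : 1 + di + grad.shape[0], 1 + dj : 1 + dj + grad.shape[1]]
            np.minimum(min_diff, np.abs(grad - nb), out=min_diff)
    return (min_diff > T).astype(np.uint8)


def local_entropy_field(image: np.ndarray, window: int = 5, bins: int = 256) -> np.ndarray:
    """Shannon entropy (bits) of the intensity histogram in a sliding window.

    Intensities in [0, 1] are quantized to ``bins`` levels; each pixel's value
    is the entropy of the level histogram over the replicate-padded
    window x window neighbourhood, in [0, log2(min(bins, window^2))].
    """
    image = _check_image(image)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    r = window // 2
    levels = np.clip((np.clip(image, 0.0, 1.0) * bins).astype(np.intp), 0, bins - 1)
    p = np.pad(levels, r, mode="edge")
    H, W = image.shape
    counts = np.zeros((H, W, bins), dtype=np.uint16)
    rr, cc = np.indices((H, W), sparse=True)
    for di in range(window):
        for dj in range(window):
            # indices are unique per shift, so fancy increment is exact
            counts[rr, cc, p[di : di + H, dj : dj + W]] += 1
    probs = counts / float(window * window)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, -probs * np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
    return terms.sum(axis=-1)


def local_roughness_field(image: np.ndarray, window: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Local roughness Q = 1 - 1/(1 + sigma^2) and the local variance field.

    sigma^2 is the population variance of the replicate-padded window, so
    0 <= Q < 1 with Q = 0 on locally constant patches.
    """
    image = _check_image(image)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    mean = ndimage.uniform_filter(image, size=window, mode="nearest")
    meansq = ndimage.uniform_filter(image * image, size=window, mode="nearest")
    sigma2 = np.clip(meansq - mean * mean, 0.0, None)
    return 1.0 - 1.0 / (1.0 + sigma2), sigma2


def minmax_normalize(fld: np.ndarray) -> np.ndarray:
    """Min-max map to [0, 1]; a constant field normalizes to all zeros."""
    fld = np.asarray(fld, dtype=float)
    lo, hi = float(fld.min()), float(fld.max())
    if hi <= lo:
        return np.zeros_like(fld)
    return (fld - lo) / (hi - lo)


def composite_feature(
    grad: np.ndarray,
    entropy: np.ndarray,
    roughness: np.ndarray,
    k1: float,
    k2: float,
    k3: float,
) -> np.ndarray:
    """Convex combination g = k1*grad + k2*entropy + k3*roughness.

    Inputs are expected already normalized to [0, 1] (see
    :func:`minmax_normalize`); the result then also lies in [0, 1].
    """
    _check_weights(k1, k2, k3)
    return k1 * np.asarray(grad, float) + k2 * np.asarray(entropy, float) + k3 * np.asarray(roughness, float)


def order_field(
    g: np.ndarray,
    R: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.7,
    clamp: bool = True,
) -> OrderField:
    """Map the composite feature and noise indicator to per-pixel orders.

    v = (-1)^R * (exp(alpha*g) - beta); with ``clamp`` (default) the magnitude
    is floored at zero, enforcing v in [0, e^alpha - beta] where R = 0 and
    [beta - e^alpha, 0] where R = 1.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if not 1.0 < beta < _E:
        raise ValueError(f"beta must lie in (1, e), got {beta}")
    g = np.asarray(g, dtype=float)
    R = np.asarray(R)
    if not np.all(np.isin(R, (0, 1))):
        raise ValueError("indicator R must be binary")
    raw = np.exp(alpha * g) - beta
    mag = np.maximum(0.0, raw) if clamp else raw
    v = np.where(R == 1, -mag, mag)
    return OrderField(v=v, R=R.astype(np.uint8), alpha=alpha, beta=beta, clamp_mode=clamp)


def compute_order_field(image: np.ndarray, params: AdaptiveParams | None = None) -> OrderField:
    """Full adaptive pathway: features -> indicator -> composite -> order field."""
    params = (params or AdaptiveParams()).validate()
    image = _check_image(image)
    grad = gradient_field(image, op=params.gradient_op)
    ent = local_entropy_field(image, window=params.window, bins=params.bins)
    rough, sigma2 = local_roughness_field(image, window=params.window)
    gn = minmax_normalize(grad)
    en = minmax_normalize(ent)
    qn = minmax_normalize(rough)
    R = noise_margin_indicator(gn, params.threshold)
    g = composite_feature(gn, en, qn, params.k1, params.k2, params.k3)
    feats = FeatureFields(
        grad=grad,
        entropy=ent,
        roughness=rough,
        sigma2=sigma2,
        grad_norm=gn,
        entropy_norm=en,
        roughness_norm=qn,
        R=R,
        T=params.threshold,
        weights=params.weights,
        g=g,
    )
    of = order_field(g, R, alpha=params.alpha, beta=params.beta, clamp=params.clamp)
    of.features = feats
    return of
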