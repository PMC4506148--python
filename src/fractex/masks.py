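"""Fractional centered-difference mask coefficients and the eight directional masks.

The symmetric (Riesz) fractional derivative of order ``v`` admits a
second-order-accurate discretization with weights

    phi_k = (-1)^k * Gamma(v+1) / (Gamma(v/2 - k + 1) * Gamma(v/2 + k + 1)),

even in ``k`` and reducing to the classical second difference ``[-1, 2, -1]``
at ``v = 2``.  Shifting each sample by ``v*h/2`` with a 3-point Lagrange
interpolant blends every node with its two neighbours, which is what gives the
operator its texture-enriching character.  Truncating the half-axis series at
``n`` terms produces a sparse 1-D coefficient line of length ``n + 2`` (one
forward cell, the centre, and ``n`` trailing cells); replicating that line
along the four axes and four diagonals yields an eight-direction mask set that
is closed under 90-degree rotation.

Everything here is deliberately dimensionless: the pixel step is ``h = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma, gammaln, gammasgn, rgamma

__all__ = [
    "DIRECTION_STEPS",
    "CenteredWeights",
    "LagrangeTriplet",
    "MaskCoefficients",
    "DirectionalMaskSet",
    "DegenerateNormalizationError",
    "phi_weights",
    "omega_weights",
    "lagrange_triplet",
    "mask_coefficients",
    "fcd1_mask_coefficients",
    "build_directional_masks",
    "normalization_denominator",
    "coefficient_table",
    "diagonal_scale",
]

#: Unit steps (row, col) of the eight mask directions.  The first four are the
#: axial directions, the last four the diagonals.  Any rotationally consistent
#: labelling is equivalent because the enhancement sums all eight responses;
#: this mapping is frozen here and used everywhere.
DIRECTION_STEPS: tuple[tuple[int, int], ...] = (
    (0, -1),
    (0, 1),
    (-1, 0),
    (1, 0),
    (1, -1),
    (-1, 1),
    (-1, -1),
    (1, 1),
)


class DegenerateNormalizationError(ValueError):
    """Raised when the mask-weight total is too close to zero to divide by."""


@dataclass(frozen=True)
class CenteredWeights:
    """Symmetric fractional centered-difference weights phi_0 .. phi_kmax.

    ``phi0_halved`` marks whether phi_0 has been divided by two for half-axis
    assembly (the centre term is shared by the two half-axis sums).
    """

    v: float
    phi: np.ndarray
    phi0_halved: bool = False

    def halved(self) -> "CenteredWeights":
        """Return a copy with phi_0 divided by 2 (idempotent)."""
        if self.phi0_halved:
            return self
        p = self.phi.copy()
        p[0] *= 0.5
        return CenteredWeights(self.v, p, phi0_halved=True)


@dataclass(frozen=True)
class LagrangeTriplet:
    """3-point Lagrange interpolation coefficients for a half-step shift v*h/2.

    Applied to the forward, centre and backward samples they reproduce any
    quadratic sequence at the shifted point exactly, and always sum to one.
    """

    a_fwd: float
    b_ctr: float
    c_bwd: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a_fwd, self.b_ctr, self.c_bwd)


@dataclass(frozen=True)
class MaskCoefficients:
    """The 1-D fractional coefficient line C_{s_k}, k = -1 .. n, for one order.

    ``scale_mode`` is "relative" (the canonical, prefactor-free form: the
    common scalar -1/(2 cos(pi v/2) h^v) of the symmetric-derivative prefactor
    cancels between the enhancement numerator and its normalization) or
    "absolute" (further divided by 2 cos(pi v/2), singular at v = 1).
    """

    v: float
    n: int
    C: np.ndarray
    scale_mode: str = "relative"

    @property
    def ks(self) -> np.ndarray:
        """Offsets k = -1 .. n matching the entries of ``C``."""
        return np.arange(-1, self.n + 1)

    @property
    def centre(self) -> float:
        """C_{s_0}, the weight on the pixel of interest."""
        return float(self.C[1])

    def to_csv(self, path) -> None:
        """Write a two-column (k, C_k) table for inspection."""
        rows = np.column_stack([self.ks.astype(float), self.C])
        np.savetxt(path, rows, delimiter=",", header="k,C_k", comments="")


@dataclass(frozen=True)
class DirectionalMaskSet:
    """Eight sparse directional masks as (row-offset, col-offset, weight) lists.

    Axial masks carry the coefficient line directly; diagonal masks scale every
    non-centre weight by 2^(-v/2) (the diagonal step-length correction) while
    the centre keeps its full weight.
    """

    v: float
    m: int
    n: int
    masks: tuple[tuple[tuple[int, int, float], ...], ...]
    direction_steps: tuple[tuple[int, int], ...] = DIRECTION_STEPS
    axial: tuple[bool, ...] = (True, True, True, True, False, False, False, False)

    @property
    def diag_scale(self) -> float:
        return float(diagonal_scale(self.v))

    def total_weight(self) -> float:
        """Brute-force sum of every weight over all eight masks."""
        return float(sum(w for mask in self.masks for (_, _, w) in mask))


def _check_order(v: float, lo: float, hi: float, closed: bool = False) -> float:
    v = float(v)
    if not np.isfinite(v):
        raise ValueError(f"fractional order must be finite, got {v!r}")
    inside = (lo <= v <= hi) if closed else (lo < v < hi)
    if not inside:
        kind = "[{}, {}]" if closed else "({}, {})"
        raise ValueError(f"fractional order v={v} outside {kind.format(lo, hi)}")
    return v


def diagonal_scale(v) -> np.ndarray | float:
    """Step-length correction 2^(-v/2) applied to non-centre diagonal weights."""
    return 2.0 ** (-np.asarray(v, dtype=float) / 2.0)


def phi_weights(v: float, kmax: int) -> CenteredWeights:
    """Fractional centered-difference weights phi_0 .. phi_kmax at order ``v``.

    phi_k = (-1)^k Gamma(v+1) / (Gamma(v/2-k+1) Gamma(v/2+k+1)); the
    reciprocal gammas are evaluated pole-safely (1/Gamma is entire, zero at
    non-positive integers), so integer orders come out exact.  Valid for
    |v| <= 2 except the Gamma(v+1) pole at v = -1.
    """
    if not isinstance(kmax, (int, np.integer)) or kmax < 1:
        raise ValueError(f"kmax must be a positive integer, got {kmax!r}")
    v = _check_order(v, -2.0, 2.0, closed=True)
    if v == -1.0:
        raise ValueError("phi weights diverge at v = -1 (Gamma(v+1) pole)")
    k = np.arange(kmax + 1)
    with np.errstate(invalid="ignore", over="ignore"):
        phi = (-1.0) ** k * gamma(v + 1.0) * rgamma(v / 2 - k + 1) * rgamma(v / 2 + k + 1)
    # beyond k ~ 160 the individual gamma factors over/underflow although the
    # weight itself decays like k^-(1+v); switch to the log-gamma form there
    big = k > 160
    if big.any():
        kb = k[big]
        logmag = (
            gammaln(v + 1.0) - gammaln(v / 2 + kb + 1) - gammaln(v / 2 - kb + 1)
        )
        sign = (-1.0) ** kb * gammasgn(v / 2 - kb + 1) * gammasgn(v / 2 + kb + 1)
        phi[big] = sign * np.exp(logmag)
    return CenteredWeights(v=v, phi=phi)


def omega_weights(v: float, kmax: int) -> np.ndarray:
    """Half-axis weights omega_0 .. omega_kmax of the split-series form.

    omega_0 = -Gamma(1-v/2) / (v Gamma(1+v/2) Gamma(-v)) and
    omega_k = (-1)^(k+1) Gamma(v/2) Gamma(1-v/2) /
              (Gamma(v/2-k+1) Gamma(v/2+k+1) Gamma(-v)).

    Defined on 0 < v < 1 only (Gamma(-v) has poles at v = 0 and v = 1).  By
    the Gamma reflection formula these reduce to omega_k = 2 cos(pi v/2) phi_k
    for k >= 1 and omega_0 = cos(pi v/2) phi_0, which makes this the
    independent oracle for :func:`phi_weights`.
    """
    if not isinstance(kmax, (int, np.integer)) or kmax < 1:
        raise ValueError(f"kmax must be a positive integer, got {kmax!r}")
    v = float(v)
    if not 0.0 < v < 1.0:
        raise ValueError(
            f"omega weights require 0 < v < 1 (Gamma(-v) pole at v in {{0, 1}}), got v={v}"
        )
    k = np.arange(1, kmax + 1)
    w0 = -gamma(1 - v / 2) / (v * gamma(1 + v / 2) * gamma(-v))
    wk = (
        (-1.0) ** (k + 1)
        * gamma(v / 2)
        * gamma(1 - v / 2)
        * rgamma(v / 2 - k + 1)
        * rgamma(v / 2 + k + 1)
        / gamma(-v)
    )
    return np.concatenate([[w0], wk])


def lagrange_triplet(v: float) -> LagrangeTriplet:
    """Lagrange 3-point coefficients for interpolating at the shift v*h/2.

    (a, b, c) = (v/4 + v^2/8, 1 - v^2/4, v^2/8 - v/4) applied to the forward,
    centre and backward neighbours; a + b + c = 1 for every v.
    """
    v = float(v)
    return LagrangeTriplet(
        a_fwd=v / 4 + v * v / 8,
        b_ctr=1 - v * v / 4,
        c_bwd=v * v / 8 - v / 4,
    )


def _assemble(phihat: np.ndarray, n: int, trip: LagrangeTriplet) -> np.ndarray:
    # Collect the truncated half-axis series (terms 0 .. n-1) by pixel offset j:
    # C_j = a*ph[j+1] (j+1 <= n-1) + b*ph[j] (j <= n-1) + c*ph[j-1] (j >= 1).
    a, b, c = trip.as_tuple()
    C = np.zeros(n + 2)
    for j in range(-1, n + 1):
        val = 0.0
        if 0 <= j + 1 <= n - 1:
            val += a * phihat[j + 1]
        if 0 <= j <= n - 1:
            val += b * phihat[j]
        if 1 <= j and j - 1 <= n - 1:
            val += c * phihat[j - 1]
        C[j + 1] = val
    return C


def _check_n(n: int) -> int:
    if not isinstance(n, (int, np.integer)) or n < 1 or n % 2 == 0:
        raise ValueError(f"truncation length n must be an odd positive integer, got {n!r}")
    return int(n)


def _apply_scale(C: np.ndarray, v: float, scale_mode: str, h: float) -> np.ndarray:
    if scale_mode == "relative":
        return -(h ** (-v)) * C
    if scale_mode == "absolute":
        if v == 1.0:
            raise ValueError("absolute scale mode is singular at v = 1 (cos(pi v/2) = 0)")
        return -(h ** (-v)) * C / (2.0 * np.cos(np.pi * v / 2))
    raise ValueError(f"unknown scale_mode {scale_mode!r}")


def mask_coefficients(
    v: float, n: int, scale_mode: str = "relative", h: float = 1.0
) -> MaskCoefficients:
    """Variable-order fractional mask coefficients C_{s_-1} .. C_{s_n}.

    Built from the halved-centre centered weights (phi_0/2 because the centre
    term is shared by both half-axis sums) recombined with the Lagrange
    triplet.  The "relative" scale (default) is -h^(-v) times the raw
    combination; "absolute" further divides by 2 cos(pi v/2).  The sum of the
    coefficients is nonzero for 0 < v < 1, which is what distinguishes a
    fractional mask from an integer-order one.
    """
    n = _check_n(n)
    v = _check_order(v, -2.0, 2.0, closed=True)
    phihat = phi_weights(v, max(n, 1)).halved().phi
    C = _assemble(phihat, n, lagrange_triplet(v))
    return MaskCoefficients(v=v, n=n, C=_apply_scale(C, v, scale_mode, h), scale_mode=scale_mode)


def fcd1_mask_coefficients(
    v: float, n: int, scale_mode: str = "relative", h: float = 1.0
) -> MaskCoefficients:
    """Fixed-order baseline: the plain truncated centered difference.

    Identical to :func:`mask_coefficients` with the Lagrange triplet forced to
    (0, 1, 0) — no half-step shift, no forward cell (C_{s_-1} = 0), the
    anterior half-axis weights phi_0/2, phi_1 .. phi_n otherwise unchanged.
    """
    n = _check_n(n)
    v = _check_order(v, -2.0, 2.0, closed=True)
    phihat = phi_weights(v, n).halved().phi
    C = np.concatenate([[0.0], phihat[: n + 1]])
    return MaskCoefficients(v=v, n=n, C=_apply_scale(C, v, scale_mode, h), scale_mode=scale_mode)


def build_directional_masks(C: MaskCoefficients, m: int) -> DirectionalMaskSet:
    """Assemble the eight directional masks from one coefficient line.

    Direction ``l`` with unit step ``u_l`` places C_{s_k} at offset ``-k*u_l``
    for k = -1 .. n, so each line runs one cell forward and ``n`` cells
    backward along its direction inside the (2m+1) x (2m+1) neighbourhood.
    Diagonal lines scale every non-centre weight by 2^(-v/2); the centre keeps
    its full weight (the split 2^(-v/2) W(0,0) + (1 - 2^(-v/2)) W(0,0)).
    """
    if C.n != 2 * m - 1:
        raise ValueError(f"mask radius m={m} requires n = 2m-1 = {2 * m - 1}, got n={C.n}")
    dscale = float(diagonal_scale(C.v))
    masks = []
    for l, (dr, dc) in enumerate(DIRECTION_STEPS):
        axial = l < 4
        entries = []
        for k in range(-1, C.n + 1):
            w = float(C.C[k + 1])
            if not axial and k != 0:
                w *= dscale
            entries.append((-k * dr, -k * dc, w))
        masks.append(tuple(entries))
    return DirectionalMaskSet(v=C.v, m=m, n=C.n, masks=tuple(masks))


def normalization_denominator(C: MaskCoefficients, v: float | None = None, eps: float = 1e-12) -> float:
    """Total mask weight D used to normalize the eight-direction response.

    D = 4 * sum_k C_k  +  2^((4-v)/2) * sum_{k != 0} C_k  +  4 * C_0,
    which equals the sum of every weight across the eight directional masks
    (2^((4-v)/2) = 4 * 2^(-v/2)).  Dividing the summed responses by D makes
    constant images exact fixed points of the enhancement.
    """
    if v is None:
        v = C.v
    S = float(C.C.sum())
    c0 = C.centre
    D = 4.0 * S + 2.0 ** ((4.0 - v) / 2.0) * (S - c0) + 4.0 * c0
    if abs(D) < eps:
        raise DegenerateNormalizationError(
            f"normalization denominator |D|={abs(D):.3e} below eps={eps:g} at v={v}"
        )
    return D


def coefficient_table(orders: np.ndarray, n: int, kind: str = "vofcd") -> np.ndarray:
    """Vectorized coefficient lines for a batch of orders, common factor removed.

    Returns an array of shape ``(len(orders), n + 2)`` holding the relative
    coefficient lines divided by Gamma(v+1).  That factor is common to every
    weight and to the normalization denominator, so the enhanced image is
    unchanged, while the entries stay finite at the Gamma pole v = -1 (inside
    the smoothing range of the adaptive order field).  ``kind`` selects the
    variable-order line ("vofcd") or the plain truncated centered difference
    ("fcd1").
    """
    v = np.atleast_1d(np.asarray(orders, dtype=float))
    if np.any(np.abs(v) >= 2):
        raise ValueError("orders must satisfy |v| < 2")
    kmax = n if kind == "fcd1" else max(n, 1)
    k = np.arange(kmax + 1)
    # phi_k / Gamma(v+1): entire in v thanks to the reciprocal-gamma form.
    ph = (-1.0) ** k * rgamma(v[:, None] / 2 - k + 1) * rgamma(v[:, None] / 2 + k + 1)
    ph[:, 0] *= 0.5
    C = np.zeros((v.size, n + 2))
    if kind == "vofcd":
        a = v / 4 + v * v / 8
        b = 1 - v * v / 4
        c = v * v / 8 - v / 4
        for j in range(-1, n + 1):
            acc = np.zeros(v.size)
            if 0 <= j + 1 <= n - 1:
                acc += a * ph[:, j + 1]
            if 0 <= j <= n - 1:
                acc += b * ph[:, j]
            if 1 <= j and j - 1 <= n - 1:
                acc += c * ph[:, j - 1]
            C[:, j + 1] = acc
    elif kind == "fcd1":
        C[:, 1:] = ph[:, : n + 1]
    else:
        raise ValueError(f"unknown coefficient kind {kind!r}")
    return -C
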