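"""Unit and property tests for the fractional mask coefficient machinery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import gamma

from fractex.masks import (
    DIRECTION_STEPS,
    DegenerateNormalizationError,
    build_directional_masks,
    coefficient_table,
    fcd1_mask_coefficients,
    lagrange_triplet,
    mask_coefficients,
    normalization_denominator,
    omega_weights,
    phi_weights,
)


def eq17_via_omega(v: float, n: int) -> np.ndarray:
    """Independent oracle: the printed coefficient formulas evaluated through
    the half-axis omega weights, prefactor -1/(2 cos(pi v/2) h^v) included."""
    w = omega_weights(v, max(n, 1))
    a, b, c = lagrange_triplet(v).as_tuple()
    C = np.zeros(n + 2)
    for j in range(-1, n + 1):
        val = 0.0
        if 0 <= j + 1 <= n - 1:
            val += a * w[j + 1]
        if 0 <= j <= n - 1:
            val += b * w[j]
        if 1 <= j <= n:
            val += c * w[j - 1]
        C[j + 1] = val
    return -C / (2.0 * np.cos(np.pi * v / 2))


class TestPhiWeights:
    def test_classical_second_difference_at_order_two(self):
        phi = phi_weights(2.0, 3).phi
        assert phi.tolist() == [2.0, -1.0, 0.0, 0.0]

    def test_even_symmetry_of_closed_form(self):
        # phi_{-k} = phi_k holds by construction; verify the closed form is
        # symmetric by evaluating it with negated k through the gamma ratio.
        v = 0.5
        phi = phi_weights(v, 5).phi
        for k in range(1, 6):
            neg = (-1.0) ** (-k) * gamma(v + 1) / (gamma(v / 2 + k + 1) * gamma(v / 2 - k + 1))
            assert phi[k] == pytest.approx(neg, abs=1e-15)

    def test_partial_sums_decay_toward_zero(self):
        # the symmetric weight series sums to zero in the limit (zero response
        # at zero frequency); brute-force partial sums over [-K, K] shrink.
        v = 0.5
        phi = phi_weights(v, 200).phi
        totals = [abs(phi[0] + 2 * phi[1 : K + 1].sum()) for K in (3, 10, 50, 200)]
        assert all(t2 < t1 for t1, t2 in zip(totals, totals[1:]))

    def test_pole_and_domain_errors(self):
        with pytest.raises(ValueError):
            phi_weights(2.5, 3)
        with pytest.raises(ValueError):
            phi_weights(-1.0, 3)
        with pytest.raises(ValueError):
            phi_weights(0.5, 0)


class TestOmegaWeights:
    def test_ratio_to_phi_is_two_cos_half_angle(self):
        v = 0.5
        w = omega_weights(v, 5)
        phi = phi_weights(v, 5).phi
        ratio = 2 * np.cos(np.pi * v / 2)
        assert w[1:] / phi[1:] == pytest.approx([ratio] * 5, rel=1e-12)
        # k = 0 is shared by both half-axis sums, so its ratio is halved
        assert w[0] / phi[0] == pytest.approx(ratio / 2, rel=1e-12)

    @pytest.mark.parametrize("v", np.arange(0.1, 1.0, 0.1).round(2).tolist())
    def test_gamma_reflection_identity(self, v):
        lhs = 1.0 / (2.0 * np.cos(np.pi * v / 2))
        rhs = gamma(v) * gamma(1 - v) / (gamma(v / 2) * gamma(1 - v / 2))
        assert abs(lhs - rhs) <= 1e-12

    def test_pole_errors_name_the_gamma_pole(self):
        for v in (0.0, 1.0, -0.3, 1.2):
            with pytest.raises(ValueError, match="Gamma"):
                omega_weights(v, 3)


class TestLagrangeTriplet:
    def test_collapses_to_centre_at_zero_and_forward_at_two(self):
        assert lagrange_triplet(0.0).as_tuple() == (0.0, 1.0, 0.0)
        assert lagrange_triplet(2.0).as_tuple() == (1.0, 0.0, 0.0)

    @given(st.floats(-2, 2, allow_nan=False))
    def test_coefficients_sum_to_one(self, v):
        a, b, c = lagrange_triplet(v).as_tuple()
        assert a + b + c == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("v", [0.3, 0.7, 1.5])
    def test_exact_on_quadratics(self, v):
        # the interpolant evaluated from (s(x+h), s(x), s(x-h)) must hit
        # s(x + v h / 2) exactly for any quadratic s
        a, b, c = lagrange_triplet(v).as_tuple()
        s = lambda x: 3.0 * x * x - 2.0 * x + 0.7
        for x in (-1.0, 0.25, 4.0):
            interp = a * s(x + 1) + b * s(x) + c * s(x - 1)
            assert interp == pytest.approx(s(x + v / 2), abs=1e-12)


class TestMaskCoefficients:
    @pytest.mark.parametrize("n", [1, 3, 5])
    @pytest.mark.parametrize("v", np.arange(0.1, 1.0, 0.1).round(2).tolist())
    def test_dual_route_against_omega_oracle(self, v, n):
        C = mask_coefficients(v, n).C
        assert np.abs(C - eq17_via_omega(v, n)).max() <= 1e-10

    def test_order_zero_limit_is_centre_only(self):
        C = mask_coefficients(1e-9, 3).C
        assert abs(C[0]) < 1e-9
        assert np.abs(C[2:]).max() < 1e-9
        assert C[1] == pytest.approx(-0.5, abs=1e-8)

    @pytest.mark.parametrize("n", [1, 3, 5])
    @pytest.mark.parametrize("v", np.arange(0.1, 1.0, 0.1).round(2).tolist())
    def test_coefficient_sum_is_nonzero(self, v, n):
        assert abs(mask_coefficients(v, n).C.sum()) > 1e-6

    def test_scale_modes_differ_by_riesz_prefactor(self):
        v = 0.4
        rel = mask_coefficients(v, 3, "relative").C
        absolute = mask_coefficients(v, 3, "absolute").C
        assert absolute * 2 * np.cos(np.pi * v / 2) == pytest.approx(rel.tolist(), rel=1e-12)

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            mask_coefficients(0.5, 4)
        with pytest.raises(ValueError):
            mask_coefficients(1.0, 3, "absolute")

    def test_table_matches_scalar_route_up_to_common_factor(self):
        orders = np.array([-0.8, -0.3, 0.2, 0.6])
        tab = coefficient_table(orders, 3)
        for row, v in zip(tab, orders):
            assert row * gamma(v + 1) == pytest.approx(
                mask_coefficients(v, 3).C.tolist(), rel=1e-12
            )

    def test_table_finite_at_negative_one(self):
        tab = coefficient_table(np.array([-1.0, -0.999, -1.001]), 3)
        assert np.all(np.isfinite(tab))


class TestFcd1Baseline:
    def test_order_two_reduces_to_half_axis_second_difference(self):
        C = fcd1_mask_coefficients(2.0, 3).C
        assert C == pytest.approx([0.0, -1.0, 1.0, 0.0, 0.0], abs=1e-14)

    def test_equals_variable_order_line_with_identity_triplet(self):
        v, n = 0.5, 3
        phihat = phi_weights(v, n).halved().phi
        expected = -np.concatenate([[0.0], phihat[: n + 1]])
        assert fcd1_mask_coefficients(v, n).C == pytest.approx(expected.tolist(), rel=1e-14)


class TestDirectionalMasks:
    def test_eight_masks_with_expected_footprint(self):
        ms = build_directional_masks(mask_coefficients(0.5, 3), m=2)
        assert len(ms.masks) == 8
        for mask, (dr, dc) in zip(ms.masks, DIRECTION_STEPS):
            assert len(mask) == 5  # n + 2 cells per line
            offs = [(r, c) for r, c, _ in mask]
            assert offs == [(-k * dr, -k * dc) for k in range(-1, 4)]

    def test_closed_under_quarter_turn(self):
        ms = build_directional_masks(mask_coefficients(0.5, 3), m=2)
        all_sets = [frozenset(mask) for mask in ms.masks]
        for mask in ms.masks:
            rotated = frozenset((c, -r, w) for r, c, w in mask)
            assert rotated in all_sets

    def test_diagonal_equals_axial_at_order_zero(self):
        ms = build_directional_masks(mask_coefficients(1e-12, 3), m=2)
        ax = sorted(w for _, _, w in ms.masks[0])
        dg = sorted(w for _, _, w in ms.masks[4])
        assert dg == pytest.approx(ax, abs=1e-12)

    def test_rejects_mismatched_radius(self):
        with pytest.raises(ValueError):
            build_directional_masks(mask_coefficients(0.5, 3), m=1)


class TestNormalizationDenominator:
    @pytest.mark.parametrize("v", [0.2, 0.5, 0.8])
    def test_equals_brute_force_weight_total(self, v):
        C = mask_coefficients(v, 3)
        ms = build_directional_masks(C, 2)
        assert normalization_denominator(C) == pytest.approx(ms.total_weight(), abs=1e-12)

    def test_order_zero_limit_is_eight_centre_weights(self):
        C = mask_coefficients(1e-10, 3)
        assert normalization_denominator(C) == pytest.approx(8 * C.centre, rel=1e-8)

    def test_scale_invariance_of_normalized_ratio(self):
        v = 0.6
        rel = mask_coefficients(v, 3, "relative")
        absolute = mask_coefficients(v, 3, "absolute")
        ratio = normalization_denominator(rel) / normalization_denominator(absolute)
        assert ratio == pytest.approx(2 * np.cos(np.pi * v / 2), rel=1e-12)

    def test_degenerate_denominator_raises(self):
        C = mask_coefficients(0.5, 3)
        with pytest.raises(DegenerateNormalizationError):
            normalization_denominator(C, eps=1e6)
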