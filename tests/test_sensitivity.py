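"""Analytic partial derivatives vs the finite-difference oracle, plus
sweep and heatmap protocols."""

import math

import numpy as np
import pytest

from mts import (
    MuscleState,
    MusculotendonParams,
    analytic_gradient,
    dF_dalpha_opt,
    dF_dlopt_fixed_pcsa,
    dF_dlopt_mt,
    fd_gradient,
    gradient_components,
    muscle_force,
    normalized_derivative,
    sensitivity_grid,
    sweep_force_curves,
)
from mts.sensitivity import mtu_length_at_lnorm

from conftest import stratified_grid

L_NORMS = (0.5, 0.8, 1.0, 1.2, 1.4)


def oracle_agreement_failures(curves, tol=1e-5):
    """Compare every analytic derivative with the central-difference oracle
    over the stratified grid; returns the list of violations.

    A mismatch counts only if it exceeds both the relative tolerance and the
    oracle's own roundoff floor ~eps*F/h (with a wide margin), which is the
    resolution limit of a central difference where the true derivative
    vanishes.
    """
    failures = []
    for params, a in stratified_grid():
        pv = params.with_(
            sigma_iso_max=45.0,
            volume=params.f_iso_max * params.l_opt_f * 100.0 / 45.0,
        )
        for l_norm in L_NORMS:
            if l_norm < math.sin(params.alpha_opt):
                continue
            l_mt = float(mtu_length_at_lnorm(params, l_norm))
            for which in ("f_iso_max", "l_opt_f", "l_opt_f_volume", "alpha_opt", "l_opt_mt"):
                p = pv if which == "l_opt_f_volume" else params
                an = analytic_gradient(which, p, l_mt, a, curves)
                if which == "alpha_opt" and p.alpha_opt == 0.0:
                    # symmetry: no first-order effect, and the oracle cannot
                    # perturb below zero
                    if an != 0.0:
                        failures.append((which, p.alpha_opt, l_norm, a, an, 0.0))
                    continue
                from mts.sensitivity import _param_value

                h = 1e-7 * _param_value(which, p)
                noise_floor = 1e-13 * p.f_iso_max / h
                fd = fd_gradient(p, l_mt, a, curves, which=which)
                mismatch = abs(an - fd)
                if mismatch == 0.0:
                    continue
                rel = mismatch / max(abs(an), abs(fd))
                if mismatch > noise_floor and rel > tol:
                    failures.append((which, p.alpha_opt, l_norm, a, an, fd))
    return failures


def test_analytic_gradients_match_oracle(curves):
    assert oracle_agreement_failures(curves) == []


class TestAlgebraicSpecializations:
    def test_dlopt_prefactor_vanishes_at_optimal_position(self, pennated, curves):
        assert dF_dlopt_fixed_pcsa(pennated, pennated.l_opt_mt, 1.0, curves) == 0.0

    def test_dlopt_unpennated_reduces_to_curve_slope_term(self, unpennated, curves):
        l_mt = unpennated.l_sla_t + 0.8 * unpennated.l_opt_f
        g = gradient_components(unpennated, l_mt, 1.0, curves)
        expected = (
            -unpennated.f_iso_max
            * (l_mt - unpennated.l_opt_mt)
            * g.E2
            / unpennated.l_opt_f ** 2
        )
        got = dF_dlopt_fixed_pcsa(unpennated, l_mt, 1.0, curves)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_volume_coupled_at_peak_is_minus_f_over_l(self, curves):
        """At the unpennated peak (E2=0, E1=1) the volume-coupled derivative
        reduces to -F_iso_max/l_opt_f: force capacity scales as 1/l_opt_f."""
        sigma, volume, l_opt_f = 50.0, 400.0, 0.05
        p = MusculotendonParams(
            f_iso_max=sigma * volume / (l_opt_f * 100.0),
            l_opt_f=l_opt_f,
            alpha_opt=0.0,
            l_opt_mt=0.30,
            sigma_iso_max=sigma,
            volume=volume,
        )
        got = analytic_gradient("l_opt_f_volume", p, p.l_opt_mt, 1.0, curves)
        assert got == pytest.approx(-p.f_iso_max / p.l_opt_f, rel=1e-12)

    def test_volume_coupled_product_rule_decomposition(self, pennated, curves):
        """d(sigma*V/l * f)/dl = -F/l * f-part + (sigma*V/l) * fixed-PCSA part."""
        l_mt = pennated.l_opt_mt + 0.01
        a = 0.8
        f_norm = muscle_force(pennated, MuscleState(l_mt, a), curves) / pennated.f_iso_max
        lhs = analytic_gradient("l_opt_f_volume", pennated, l_mt, a, curves)
        rhs = (
            -pennated.f_iso_max / pennated.l_opt_f * f_norm
            + dF_dlopt_fixed_pcsa(pennated, l_mt, a, curves)
        )
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_pennation_derivative_zero_at_zero_angle(self, unpennated, curves):
        l_mt = unpennated.l_sla_t + 0.9 * unpennated.l_opt_f
        assert dF_dalpha_opt(unpennated, l_mt, 1.0, curves) == 0.0

    def test_pennation_derivative_negative_below_optimal(self, pennated, curves):
        l_mt = float(mtu_length_at_lnorm(pennated, 0.95))
        assert dF_dalpha_opt(pennated, l_mt, 1.0, curves) < 0.0

    def test_tendon_side_zero_at_stationary_point(self, unpennated, curves):
        # unpennated, l_norm = 1: active slope zero, passive slack -> E2 = 0
        assert dF_dlopt_mt(unpennated, unpennated.l_opt_mt, 1.0, curves) == pytest.approx(
            0.0, abs=1e-9 * unpennated.f_iso_max
        )

    def test_tendon_side_is_negative_curve_slope_on_ascending_limb(
        self, unpennated, curves
    ):
        l_mt = unpennated.l_sla_t + 0.8 * unpennated.l_opt_f
        g = gradient_components(unpennated, l_mt, 1.0, curves)
        assert g.E2 > 0
        got = dF_dlopt_mt(unpennated, l_mt, 1.0, curves)
        assert got == pytest.approx(
            -unpennated.f_iso_max * g.E2 / unpennated.l_opt_f, rel=1e-12
        )


class TestFiniteDifferenceOracle:
    def test_exact_for_linear_parameter(self, pennated, curves):
        """Force is linear in F_iso_max, so the central difference is exact."""
        l_mt = pennated.l_opt_mt + 0.005
        fd = fd_gradient(pennated, l_mt, 1.0, curves, which="f_iso_max")
        an = analytic_gradient("f_iso_max", pennated, l_mt, 1.0, curves)
        assert fd == pytest.approx(an, rel=1e-8)

    def test_second_order_convergence(self, pennated, curves):
        """Halving h shrinks the truncation error ~4x in the smooth regime."""
        l_mt = pennated.l_opt_mt + 0.01
        exact = analytic_gradient("l_opt_mt", pennated, l_mt, 1.0, curves)
        h0 = 1e-3 * pennated.l_opt_mt
        e1 = abs(fd_gradient(pennated, l_mt, 1.0, curves, "l_opt_mt", h0) - exact)
        e2 = abs(fd_gradient(pennated, l_mt, 1.0, curves, "l_opt_mt", h0 / 2) - exact)
        assert e2 == pytest.approx(e1 / 4.0, rel=0.15)

    def test_infeasible_perturbation_errors_after_one_retry(self, unpennated, curves):
        l_mt = unpennated.l_sla_t + 0.9 * unpennated.l_opt_f
        with pytest.raises(ValueError):
            fd_gradient(unpennated, l_mt, 1.0, curves, which="alpha_opt")


class TestNormalizedDerivative:
    def test_zero_where_derivative_zero(self, pennated, curves):
        assert normalized_derivative("l_opt_f", pennated, pennated.l_opt_mt, 1.0, curves) == 0.0

    def test_zero_pennation_sensitivity_unpennated(self, unpennated, curves):
        l_mt = unpennated.l_sla_t + 0.9 * unpennated.l_opt_f
        assert normalized_derivative("alpha_opt", unpennated, l_mt, 1.0, curves) == 0.0

    @pytest.mark.parametrize("which", ["f_iso_max", "l_opt_f", "alpha_opt", "l_opt_mt"])
    def test_first_order_taylor_prediction(self, which, pennated, curves):
        """F(theta*(1+eps)) - F(theta) ~ normalized * eps * F_iso_max."""
        from mts.sensitivity import _perturbed

        l_mt = pennated.l_opt_mt + 0.008
        a = 1.0
        eps = 1e-6
        nd = normalized_derivative(which, pennated, l_mt, a, curves)
        theta = {
            "f_iso_max": pennated.f_iso_max,
            "l_opt_f": pennated.l_opt_f,
            "alpha_opt": pennated.alpha_opt,
            "l_opt_mt": pennated.l_opt_mt,
        }[which]
        p2 = _perturbed(which, pennated, theta * (1 + eps))
        df = muscle_force(p2, MuscleState(l_mt, a), curves) - muscle_force(
            pennated, MuscleState(l_mt, a), curves
        )
        assert df == pytest.approx(
            nd * eps * pennated.f_iso_max, rel=1e-4, abs=1e-7 * pennated.f_iso_max
        )

    def test_unknown_parameter_id(self, pennated):
        with pytest.raises(ValueError, match="unknown parameter id"):
            normalized_derivative("l_sla_t", pennated, 0.41, 1.0)


class TestSweep:
    def test_zero_variation_reproduces_baseline(self, pennated, curves):
        df = sweep_force_curves(pennated, "l_opt_f", [0.0], a=1.0, curves=curves)
        sub = df[(df.parameter == "l_opt_f") & (df.variation == 0.0)]
        base = df[(df.parameter == "reference_band") & (df.variation == 0.1)]
        np.testing.assert_allclose(sub.value.values, base.value.values / 1.1, rtol=1e-12)

    def test_f_iso_max_variation_scales_curve_exactly(self, pennated, curves):
        df = sweep_force_curves(pennated, "f_iso_max", [0.0, -0.1, 0.1], curves=curves)
        by = {
            v: df[(df.parameter == "f_iso_max") & (df.variation == v)].value.values
            for v in (0.0, -0.1, 0.1)
        }
        np.testing.assert_allclose(by[0.1], by[0.0] * 1.1, rtol=1e-12)
        np.testing.assert_allclose(by[-0.1], by[0.0] * 0.9, rtol=1e-12)

    def test_infeasible_points_flagged(self, curves):
        p = MusculotendonParams(
            f_iso_max=800.0, l_opt_f=0.05, alpha_opt=math.radians(30), l_opt_mt=0.25
        )
        # l_norm below sin(30 deg) = 0.5 cannot be reached
        df = sweep_force_curves(
            p, "l_opt_mt", [0.0], l_norm_grid=np.linspace(0.35, 1.5, 50), curves=curves
        )
        assert df.l_norm.min() >= 0.5 - 1e-12

    def test_tidy_schema(self, pennated, curves):
        df = sweep_force_curves(pennated, "alpha_opt", [0.1], curves=curves)
        assert list(df.columns) == ["parameter", "variation", "l_norm", "value"]
        assert set(df.parameter) == {"alpha_opt", "reference_band"}


class TestSensitivityGrid:
    def test_matches_pointwise_calls(self, pennated, curves):
        p_ax = np.array([0.04, 0.05, 0.06])
        l_ax = np.array([0.38, 0.40, 0.42])
        g = sensitivity_grid("l_opt_f", pennated, p_ax, l_ax, 1.0, curves)
        for i, theta in enumerate(p_ax):
            p_i = pennated.with_(l_opt_f=theta, sigma_iso_max=None, volume=None)
            for j, lmt in enumerate(l_ax):
                assert g.matrix[i, j] == pytest.approx(
                    normalized_derivative("l_opt_f", p_i, lmt, 1.0, curves), rel=1e-12
                )
        tidy = g.to_frame()
        assert len(tidy) == g.matrix.size
        assert np.isfinite(g.matrix).all()

    def test_vanishing_pennation_row_is_zero(self, curves):
        p = MusculotendonParams(
            f_iso_max=800.0, l_opt_f=0.05, alpha_opt=math.radians(10), l_opt_mt=0.30
        )
        g = sensitivity_grid(
            "alpha_opt",
            p,
            np.array([1e-9, math.radians(10.0)]),
            np.array([0.29, 0.30, 0.31]),
            1.0,
            curves,
        )
        assert np.abs(g.matrix[0]).max() < 1e-7

    def test_rejects_bad_axes(self, pennated):
        with pytest.raises(ValueError, match="strictly increasing"):
            sensitivity_grid("l_opt_f", pennated, np.array([0.06, 0.05]), np.array([0.4]))
        with pytest.raises(ValueError, match="nonempty"):
            sensitivity_grid("l_opt_f", pennated, np.array([]), np.array([0.4]))
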