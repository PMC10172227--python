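"""Analytic sensitivity of isometric muscle force to musculotendon parameters.

The partial derivatives of the rigid-tendon Hill-type force with respect to
the four musculotendon parameters are available in closed form.  With
``s = l_mt - l_sla_t`` and ``h = l_opt_f*sin(alpha_opt)`` they share three
intermediates:

    E1 = f_pe + a*f_ce                     (curve value)
    E2 = df_pe/dl_norm + a*df_ce/dl_norm   (curve slope)
    E3 = s^2 + h^2                         (squared fiber length)

Differentiation convention: ``l_opt_mt`` (MTU length at the optimal joint
position) is the free tendon-side parameter and the tendon slack length is
always its dependent quantity, ``l_sla_t = l_opt_mt - l_opt_f*cos(alpha_opt)``.
Every derivative here was verified symbolically and is continuously checked
against the central finite-difference oracle :func:`fd_gradient`.

Two closed forms exist for the optimal-fiber-length derivative: one treating
the maximal isometric force as an independent parameter (fixed PCSA), one
propagating PCSA = V/l_opt_f so that F_iso_max = sigma*V/l_opt_f co-varies
(volume-coupled PCSA).

Normalizing a derivative as (dF/dtheta)*theta/F_iso_max gives the fractional
change of force capacity (in units of F_iso_max) per fractional parameter
change, the scale on which parameters are compared: the tendon-side
parameter dominates, pennation angle matters least.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .core import (
    DegenerateFiberError,
    MuscleState,
    MusculotendonParams,
    muscle_force,
)
from .curves import CharacteristicCurves, default_curves

__all__ = [
    "PARAMETER_IDS",
    "GradientComponents",
    "SensitivityGrid",
    "gradient_components",
    "dF_df_iso_max",
    "dF_dlopt_fixed_pcsa",
    "dF_dlopt_volume_pcsa",
    "dF_dalpha_opt",
    "dF_dlopt_mt",
    "analytic_gradient",
    "normalized_derivative",
    "fd_gradient",
    "sweep_force_curves",
    "mtu_length_at_lnorm",
    "sensitivity_grid",
]

logger = logging.getLogger("mts.sensitivity")

#: Parameter identifiers accepted by the gradient/normalization routines.
PARAMETER_IDS = ("f_iso_max", "l_opt_f", "l_opt_f_volume", "alpha_opt", "l_opt_mt")


@dataclass(frozen=True)
class GradientComponents:
    """E1/E2/E3 intermediates shared by the analytic derivatives."""

    E1: float  # f_pe + a*f_ce (dimensionless)
    E2: float  # curve slope sum (dimensionless)
    E3: float  # squared fiber length (m^2)
    l_norm: float
    s: float  # l_mt - l_sla_t (m)
    h: float  # l_opt_f*sin(alpha_opt) (m)


def gradient_components(
    params: MusculotendonParams,
    l_mt: float,
    a: float,
    curves: CharacteristicCurves | None = None,
) -> GradientComponents:
    """Evaluate E1, E2, E3 at the given MTU length and activation."""
    if curves is None:
        curves = default_curves()
    s = l_mt - params.l_sla_t
    h = params.l_opt_f * math.sin(params.alpha_opt)
    if h == 0.0 and s <= 0.0:
        raise DegenerateFiberError(
            f"fiber length nonpositive at l_mt={l_mt:g} m with zero pennation"
        )
    E3 = s * s + h * h
    l_norm = math.sqrt(E3) / params.l_opt_f
    E1 = float(curves.passive_fl(l_norm)) + a * float(curves.active_fl(l_norm))
    E2 = float(curves.d_passive_fl(l_norm)) + a * float(curves.d_active_fl(l_norm))
    return GradientComponents(E1=E1, E2=E2, E3=E3, l_norm=l_norm, s=s, h=h)


# ---------------------------------------------------------------------------
# analytic partial derivatives


def dF_df_iso_max(params, l_mt, a, curves=None) -> float:
    """dF/dF_iso_max = F/F_iso_max (force is linear in its capacity)."""
    return muscle_force(params, MuscleState(l_mt, a), curves) / params.f_iso_max


def dF_dlopt_fixed_pcsa(
    params: MusculotendonParams, l_mt: float, a: float, curves=None
) -> float:
    """dF/dl_opt_f with F_iso_max independent of l_opt_f (N/m).

    -F_iso_max*(l_mt - l_opt_mt) * ( E1*l_opt_f*sin^2(alpha_opt)/E3^{3/2}
                                    + E2*s^2/(E3*l_opt_f^2) )
    Vanishes at the optimal joint position (l_mt = l_opt_mt).
    """
    g = gradient_components(params, l_mt, a, curves)
    lf = params.l_opt_f
    sin2 = math.sin(params.alpha_opt) ** 2
    return -params.f_iso_max * (l_mt - params.l_opt_mt) * (
        g.E1 * lf * sin2 / g.E3 ** 1.5 + g.E2 * g.s ** 2 / (g.E3 * lf ** 2)
    )


def dF_dlopt_volume_pcsa(
    params: MusculotendonParams, l_mt: float, a: float, curves=None
) -> float:
    """dF/dl_opt_f with PCSA = V/l_opt_f propagated, F_iso_max = sigma*V/l_opt_f.

    Requires ``sigma_iso_max`` and ``volume`` on the parameter set.  The
    product sigma*V enters only through F_iso_max*l_opt_f, so the expression
    is evaluated in SI via that identity.
    """
    if params.sigma_iso_max is None or params.volume is None:
        raise ValueError(
            "volume-coupled derivative needs sigma_iso_max and volume on params"
        )
    g = gradient_components(params, l_mt, a, curves)
    lf = params.l_opt_f
    d = l_mt - params.l_opt_mt
    sigma_v = params.f_iso_max * lf  # sigma*V in SI (N*m)
    return -(sigma_v / lf ** 2) * (
        g.E1 * (g.E3 * g.s + g.h ** 2 * d) / g.E3 ** 1.5
        + g.E2 * d * g.s ** 2 / (g.E3 * lf)
    )


def dF_dalpha_opt(
    params: MusculotendonParams, l_mt: float, a: float, curves=None
) -> float:
    """dF/dalpha_opt at fixed l_opt_mt (N/rad); zero at alpha_opt = 0.

    Carries the overall sin(alpha_opt) prefactor:

    -F_iso_max*sin(a_opt) * ( E1*l_f^2*(l_f + (l_mt-l_opt_mt)*cos(a_opt))/E3^{3/2}
                             + E2*(l_mt-l_opt_mt)*s/E3 )
    """
    g = gradient_components(params, l_mt, a, curves)
    lf = params.l_opt_f
    d = l_mt - params.l_opt_mt
    return -params.f_iso_max * math.sin(params.alpha_opt) * (
        g.E1 * lf ** 2 * (lf + d * math.cos(params.alpha_opt)) / g.E3 ** 1.5
        + g.E2 * d * g.s / g.E3
    )


def dF_dlopt_mt(
    params: MusculotendonParams, l_mt: float, a: float, curves=None
) -> float:
    """dF/dl_opt_mt, the tendon-side (phase-shift) sensitivity (N/m).

    -F_iso_max * ( E1*(l_opt_f*sin(a_opt))^2/E3^{3/2} + E2*s^2/(E3*l_opt_f) )

    At alpha_opt = 0 this reduces to -F_iso_max*E2/l_opt_f: shifting the
    joint position of fiber optimality slides the expressed force-length
    curve, so the sensitivity is the (negative) local curve slope.
    """
    g = gradient_components(params, l_mt, a, curves)
    lf = params.l_opt_f
    return -params.f_iso_max * (
        g.E1 * g.h ** 2 / g.E3 ** 1.5 + g.E2 * g.s ** 2 / (g.E3 * lf)
    )


_ANALYTIC = {
    "f_iso_max": dF_df_iso_max,
    "l_opt_f": dF_dlopt_fixed_pcsa,
    "l_opt_f_volume": dF_dlopt_volume_pcsa,
    "alpha_opt": dF_dalpha_opt,
    "l_opt_mt": dF_dlopt_mt,
}


def analytic_gradient(which: str, params, l_mt, a, curves=None) -> float:
    """Dispatch an analytic partial derivative by parameter id."""
    try:
        fn = _ANALYTIC[which]
    except KeyError:
        raise ValueError(f"unknown parameter id {which!r}; use one of {PARAMETER_IDS}")
    return fn(params, l_mt, a, curves)


def _param_value(which: str, params: MusculotendonParams) -> float:
    try:
        return {
            "f_iso_max": params.f_iso_max,
            "l_opt_f": params.l_opt_f,
            "l_opt_f_volume": params.l_opt_f,
            "alpha_opt": params.alpha_opt,
            "l_opt_mt": params.l_opt_mt,
        }[which]
    except KeyError:
        raise ValueError(
            f"unknown parameter id {which!r}; use one of {PARAMETER_IDS}"
        ) from None


def normalized_derivative(
    which: str, params: MusculotendonParams, l_mt: float, a: float, curves=None
) -> float:
    """(dF/dtheta)*theta/F_iso_max: fractional force change (in units of
    F_iso_max) per fractional change of the parameter.

    A value of 10 means a small fractional increase eps of the parameter
    raises the estimated force capacity at this muscle length by 10*eps of
    the maximal isometric force.
    """
    theta = _param_value(which, params)
    if theta < 0:
        raise ValueError("parameter value must be nonnegative")
    return analytic_gradient(which, params, l_mt, a, curves) * theta / params.f_iso_max


# ---------------------------------------------------------------------------
# finite-difference oracle


def _perturbed(which: str, params: MusculotendonParams, theta: float):
    """Rebuild a parameter set with one parameter moved to ``theta``.

    l_opt_mt stays the free tendon-side parameter; l_sla_t always follows.
    Parameters whose perturbation would break the sigma*V/l_opt_f
    consistency are perturbed on a copy without the volume annotation.
    """
    if which == "f_iso_max":
        return params.with_(f_iso_max=theta, sigma_iso_max=None, volume=None)
    if which == "l_opt_f":
        return params.with_(l_opt_f=theta, sigma_iso_max=None, volume=None)
    if which == "l_opt_f_volume":
        if params.sigma_iso_max is None:
            raise ValueError("volume-coupled perturbation needs sigma/volume")
        f_new = params.sigma_iso_max * params.volume / (theta * 100.0)
        return params.with_(l_opt_f=theta, f_iso_max=f_new)
    if which == "alpha_opt":
        return params.with_(alpha_opt=theta)
    if which == "l_opt_mt":
        return params.with_(l_opt_mt=theta)
    raise ValueError(f"unknown parameter id {which!r}; use one of {PARAMETER_IDS}")


def fd_gradient(
    params: MusculotendonParams,
    l_mt: float,
    a: float,
    curves=None,
    which: str = "l_opt_mt",
    h: float | None = None,
) -> float:
    """Central finite difference of muscle force w.r.t. one parameter.

    O(h^2) accurate; default step 1e-7 times the parameter magnitude.  Used
    as the independent oracle for the analytic expressions in tests and
    diagnostics.  If a perturbation leaves the feasible parameter region the
    step is reduced once (factor 10), then a ValueError propagates.
    """
    theta = _param_value(which, params)
    if h is None:
        h = 1e-7 * (abs(theta) if theta != 0.0 else 1.0)
    for attempt in range(2):
        try:
            p_plus = _perturbed(which, params, theta + h)
            p_minus = _perturbed(which, params, theta - h)
            f_plus = muscle_force(p_plus, MuscleState(l_mt, a), curves)
            f_minus = muscle_force(p_minus, MuscleState(l_mt, a), curves)
            return (f_plus - f_minus) / (2.0 * h)
        except (ValueError, DegenerateFiberError):
            if attempt == 1:
                raise
            h /= 10.0


# ---------------------------------------------------------------------------
# parameter-variation sweeps and sensitivity grids


def mtu_length_at_lnorm(params: MusculotendonParams, l_norm) -> np.ndarray:
    """Invert the fiber geometry: MTU length at given normalized fiber length.

    l_mt = l_sla_t + l_opt_f*sqrt(l_norm^2 - sin^2(alpha_opt)); requires
    l_norm >= sin(alpha_opt) (the fiber cannot be shorter than the constant
    muscle thickness).  Infeasible entries come back NaN.
    """
    l = np.asarray(l_norm, dtype=float)
    sin_a = math.sin(params.alpha_opt)
    with np.errstate(invalid="ignore"):
        proj = np.sqrt(l ** 2 - sin_a ** 2)
    return params.l_sla_t + params.l_opt_f * proj


def _sweep_variant(
    which: str, params: MusculotendonParams, v: float
) -> MusculotendonParams:
    """Parameter set for sweep variation fraction ``v``.

    Sweeps vary each quantity with the baseline's geometric primitives
    (F_iso_max, l_opt_f, alpha_opt, l_sla_t) otherwise held fixed; the
    tendon-side variation shifts l_opt_mt (one-to-one with l_sla_t).
    """
    l_sla = params.l_sla_t
    if which == "f_iso_max":
        return params.with_(
            f_iso_max=params.f_iso_max * (1.0 + v), sigma_iso_max=None, volume=None
        )
    if which in ("l_opt_f", "l_opt_f_volume"):
        lf = params.l_opt_f * (1.0 + v)
        l_opt_mt = l_sla + lf * math.cos(params.alpha_opt)
        if which == "l_opt_f":
            return params.with_(
                l_opt_f=lf, l_opt_mt=l_opt_mt, sigma_iso_max=None, volume=None
            )
        f_new = params.f_iso_max / (1.0 + v)  # sigma*V fixed, PCSA ~ 1/l_opt_f
        return params.with_(l_opt_f=lf, f_iso_max=f_new, l_opt_mt=l_opt_mt)
    if which == "alpha_opt":
        alpha = params.alpha_opt * (1.0 + v)
        l_opt_mt = l_sla + params.l_opt_f * math.cos(alpha)
        return params.with_(alpha_opt=alpha, l_opt_mt=l_opt_mt)
    if which == "l_opt_mt":
        return params.with_(l_opt_mt=params.l_opt_mt * (1.0 + v))
    raise ValueError(f"unknown parameter id {which!r}; use one of {PARAMETER_IDS}")


def sweep_force_curves(
    params: MusculotendonParams,
    which: str,
    variations: Sequence[float],
    l_norm_range: tuple[float, float] = (0.35, 1.50),
    n: int = 200,
    a: float = 1.0,
    curves: CharacteristicCurves | None = None,
    l_norm_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Family of normalized force-length curves under parameter variations.

    The MTU-length grid is fixed by mapping the *baseline* normalized fiber
    lengths in ``l_norm_range`` (or an explicit ``l_norm_grid``) through the
    baseline geometry; every variation is evaluated on that same grid and
    normalized by the baseline F_iso_max, so curve shifts are directly
    comparable to the +/-10% and +/-20% F_iso_max reference bands that are
    appended (parameter "reference_band").

    Returns a tidy frame with columns parameter, variation, l_norm, value.
    Variation 0 reproduces the baseline curve exactly; infeasible points
    are NaN and fully infeasible variations are skipped with a warning.
    """
    if l_norm_grid is None:
        l_norm_grid = np.linspace(l_norm_range[0], l_norm_range[1], n)
    l_norm_grid = np.asarray(l_norm_grid, dtype=float)
    sin_a = math.sin(params.alpha_opt)
    feasible = l_norm_grid >= sin_a
    if not feasible.all():
        logger.warning(
            "dropping %d grid points with l_norm < sin(alpha_opt)=%.3f",
            int((~feasible).sum()),
            sin_a,
        )
        l_norm_grid = l_norm_grid[feasible]
    l_mt_grid = mtu_length_at_lnorm(params, l_norm_grid)
    f0 = params.f_iso_max

    def curve_for(p: MusculotendonParams) -> np.ndarray:
        out = np.empty_like(l_mt_grid)
        for i, lmt in enumerate(l_mt_grid):
            try:
                out[i] = muscle_force(p, MuscleState(lmt, a), curves) / f0
            except DegenerateFiberError:
                out[i] = np.nan
        return out

    frames: List[pd.DataFrame] = []
    for v in variations:
        try:
            p_v = _sweep_variant(which, params, v)
        except ValueError as exc:
            logger.warning("variation %+g for %s skipped: %s", v, which, exc)
            continue
        vals = curve_for(p_v)
        if np.isnan(vals).all():
            logger.warning("variation %+g for %s infeasible everywhere", v, which)
            continue
        frames.append(
            pd.DataFrame(
                {
                    "parameter": which,
                    "variation": v,
                    "l_norm": l_norm_grid,
                    "value": vals,
                }
            )
        )
    # +/-10% and +/-20% force-capacity reference bands around the baseline
    base = curve_for(params)
    for v in (-0.2, -0.1, 0.1, 0.2):
        frames.append(
            pd.DataFrame(
                {
                    "parameter": "reference_band",
                    "variation": v,
                    "l_norm": l_norm_grid,
                    "value": base * (1.0 + v),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SensitivityGrid:
    """Normalized-derivative heatmap data for one parameter.

    ``matrix[i, j]`` is the normalized partial derivative with the swept
    parameter at ``param_axis[i]`` evaluated at MTU length ``l_axis[j]``.
    """

    which: str
    param_axis: np.ndarray
    l_axis: np.ndarray
    matrix: np.ndarray
    a: float
    meta: Dict[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (parameter, param_value, l_mt, value)."""
        pi, li = np.meshgrid(
            np.arange(len(self.param_axis)), np.arange(len(self.l_axis)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "parameter": self.which,
                "param_value": self.param_axis[pi.ravel()],
                "l_mt": self.l_axis[li.ravel()],
                "value": self.matrix.ravel(),
            }
        )


def sensitivity_grid(
    which: str,
    params_template: MusculotendonParams,
    param_axis: Sequence[float],
    l_axis: Sequence[float],
    a: float = 1.0,
    curves: CharacteristicCurves | None = None,
) -> SensitivityGrid:
    """Normalized partial derivatives over a parameter x MTU-length grid.

    Each row substitutes one value of the swept parameter into the template
    (l_opt_mt free / l_sla_t dependent convention); infeasible grid points
    are flagged NaN and logged.
    """
    p_ax = np.asarray(param_axis, dtype=float)
    l_ax = np.asarray(l_axis, dtype=float)
    if p_ax.size == 0 or l_ax.size == 0:
        raise ValueError("axes must be nonempty")
    if np.any(np.diff(p_ax) <= 0) or np.any(np.diff(l_ax) <= 0):
        raise ValueError("axes must be strictly increasing")
    mat = np.full((p_ax.size, l_ax.size), np.nan)
    for i, theta in enumerate(p_ax):
        try:
            p_i = _perturbed(which, params_template, theta)
        except (ValueError, DegenerateFiberError) as exc:
            logger.warning("grid row %s=%g infeasible: %s", which, theta, exc)
            continue
        for j, lmt in enumerate(l_ax):
            try:
                mat[i, j] = normalized_derivative(which, p_i, lmt, a, curves)
            except (ValueError, DegenerateFiberError):
                logger.warning("grid point (%s=%g, l_mt=%g) infeasible", which, theta, lmt)
    return SensitivityGrid(
        which=which,
        param_axis=p_ax,
        l_axis=l_ax,
        matrix=mat,
        a=a,
        meta={"template": params_template.name or "unnamed"},
    )
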