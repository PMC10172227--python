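"""Isometric rigid-tendon Hill-type muscle force.

The muscle-tendon unit (MTU) is a fiber of optimal length ``l_opt_f``
pennated at ``alpha_opt``, in series with a rigid tendon of slack length
``l_sla_t``.  Under the rigid-tendon assumption every change of MTU length
``l_mt`` is absorbed by the fiber, and with constant muscle thickness the
fiber endpoints satisfy

    fiber^2 = (l_mt - l_sla_t)^2 + (l_opt_f * sin(alpha_opt))^2

which yields the pennation angle at any MTU length and the normalized fiber
length used by the characteristic curves.  Muscle force is

    F = F_iso_max * cos(alpha(l_mt)) * (f_pe(l_norm) + a * f_ce(l_norm))

i.e. the isometric specialization of the Hill-type contraction dynamics:
the force-velocity multiplier is fixed at unity (see
:data:`VELOCITY_MULTIPLIER`), the documented hook for future extension.

Internal units are SI throughout (m, N, rad); degrees, N/cm^2 and cm^3 are
accepted only at I/O boundaries with explicit conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .curves import CharacteristicCurves, default_curves

__all__ = [
    "DegenerateFiberError",
    "MusculotendonParams",
    "MuscleState",
    "VELOCITY_MULTIPLIER",
    "pennation_at_length",
    "normalized_fiber_length",
    "muscle_force",
    "tendon_slack_length",
]

#: Force-velocity multiplier of the contraction dynamics.  The whole
#: sensitivity analysis is isometric, so this is hard-set to 1; replace the
#: constant with a velocity-dependent factor to extend the model.
VELOCITY_MULTIPLIER: float = 1.0

# Relative tolerance for the internal-consistency checks of parameter sets.
_SLACK_RTOL = 1e-12
_FORCE_RTOL = 1e-9


class DegenerateFiberError(ValueError):
    """Fiber length is nonpositive (unpennated fiber with l_mt <= l_sla_t)."""


def tendon_slack_length(l_opt_mt: float, l_opt_f: float, alpha_opt: float) -> float:
    """Tendon slack length from the MTU length at the optimal joint position.

    l_sla_t = l_opt_mt - l_opt_f * cos(alpha_opt).  In modeling, this
    parameter acts as a phase shift fixing the joint position at which the
    fiber reaches optimal length, rather than an anatomical tendon length.
    """
    if l_opt_mt <= 0 or l_opt_f <= 0:
        raise ValueError("lengths must be positive")
    if not 0.0 <= alpha_opt < math.pi / 2:
        raise ValueError("alpha_opt must be in [0, pi/2)")
    l_sla = l_opt_mt - l_opt_f * math.cos(alpha_opt)
    if l_sla <= 0.0:
        raise ValueError("optimal MTU length shorter than projected fiber")
    return l_sla


@dataclass(frozen=True)
class MusculotendonParams:
    """The four Hill-type musculotendon parameters (SI units).

    ``l_opt_mt`` is the MTU length at the optimal joint position; the tendon
    slack length is its dependent quantity, ``l_sla_t = l_opt_mt -
    l_opt_f*cos(alpha_opt)``.  When the maximal isometric force is derived
    from muscle volume, ``sigma_iso_max`` (N/cm^2) and ``volume`` (cm^3) may
    be carried so that the volume-coupled sensitivity of force to optimal
    fiber length is available.
    """

    f_iso_max: float  # N
    l_opt_f: float  # m
    alpha_opt: float  # rad
    l_opt_mt: float  # m
    sigma_iso_max: Optional[float] = None  # N/cm^2
    volume: Optional[float] = None  # cm^3
    name: str = ""

    def __post_init__(self) -> None:
        if self.f_iso_max <= 0:
            raise ValueError("f_iso_max must be positive")
        if self.l_opt_f <= 0 or self.l_opt_mt <= 0:
            raise ValueError("lengths must be positive")
        if not 0.0 <= self.alpha_opt < math.pi / 2:
            raise ValueError("alpha_opt must be in [0, pi/2)")
        # validates l_opt_mt > l_opt_f cos(alpha_opt)
        tendon_slack_length(self.l_opt_mt, self.l_opt_f, self.alpha_opt)
        if (self.sigma_iso_max is None) != (self.volume is None):
            raise ValueError("sigma_iso_max and volume must be given together")
        if self.sigma_iso_max is not None:
            if self.sigma_iso_max <= 0 or self.volume <= 0:
                raise ValueError("sigma_iso_max and volume must be positive")
            # sigma [N/cm^2] * V [cm^3] / l_opt_f [cm] -> N
            implied = self.sigma_iso_max * self.volume / (self.l_opt_f * 100.0)
            if abs(implied - self.f_iso_max) > _FORCE_RTOL * self.f_iso_max:
                raise ValueError(
                    "f_iso_max inconsistent with sigma_iso_max*volume/l_opt_f: "
                    f"{self.f_iso_max:g} N vs {implied:g} N"
                )

    @property
    def l_sla_t(self) -> float:
        """Tendon slack length (m), always the dependent quantity."""
        return self.l_opt_mt - self.l_opt_f * math.cos(self.alpha_opt)

    def with_(self, **changes) -> "MusculotendonParams":
        """Return a copy with fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class MuscleState:
    """Instantaneous MTU length (m) and activation (0..1)."""

    l_mt: float
    a: float = 1.0

    def __post_init__(self) -> None:
        if self.l_mt <= 0:
            raise ValueError("l_mt must be positive")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("activation must be in [0, 1]")


def _fiber_geometry(params: MusculotendonParams, l_mt: float):
    """Return (s, h, fiber) with s = l_mt - l_sla_t, h the constant muscle
    thickness l_opt_f*sin(alpha_opt), fiber = sqrt(s^2 + h^2).

    fiber**2 is the E3 intermediate of the analytic sensitivity expressions.
    """
    if l_mt <= 0:
        raise ValueError("l_mt must be positive")
    s = l_mt - params.l_sla_t
    h = params.l_opt_f * math.sin(params.alpha_opt)
    if h == 0.0 and s <= 0.0:
        raise DegenerateFiberError(
            "MTU shorter than slack tendon with zero pennation: "
            f"l_mt={l_mt:g} m <= l_sla_t={params.l_sla_t:g} m"
        )
    return s, h, math.hypot(s, h)


def pennation_at_length(params: MusculotendonParams, l_mt: float) -> float:
    """Pennation angle at MTU length ``l_mt`` (rad), constant-thickness model.

    alpha(l_mt) = atan2(l_opt_f*sin(alpha_opt), l_mt - l_sla_t), in [0, pi).
    At ``l_mt = l_opt_mt`` this returns exactly ``alpha_opt``; for a fiber
    pushed past perpendicular (s < 0 with pennation) the angle exceeds 90
    degrees.
    """
    s, h, _ = _fiber_geometry(params, l_mt)
    return math.atan2(h, s)


def normalized_fiber_length(params: MusculotendonParams, l_mt: float) -> float:
    """Fiber length at ``l_mt`` divided by optimal fiber length.

    Computed from the constant-thickness geometry,
    sqrt((l_mt - l_sla_t)^2 + (l_opt_f*sin(alpha_opt))^2) / l_opt_f,
    which is robust where the projection form
    (l_mt - l_sla_t)/(l_opt_f*cos(alpha)) degenerates, and equal to it
    wherever the latter is defined.
    """
    _, _, fiber = _fiber_geometry(params, l_mt)
    return fiber / params.l_opt_f


def muscle_force(
    params: MusculotendonParams,
    state: MuscleState,
    curves: CharacteristicCurves | None = None,
) -> float:
    """Isometric rigid-tendon muscle force (N).

    F = F_iso_max * cos(alpha(l_mt)) * (f_pe(l_norm) + a*f_ce(l_norm)),
    with the force-velocity multiplier fixed at 1.
    """
    if curves is None:
        curves = default_curves()
    s, _, fiber = _fiber_geometry(params, state.l_mt)
    l_norm = fiber / params.l_opt_f
    cos_alpha = s / fiber
    f_len = float(curves.passive_fl(l_norm)) + state.a * float(curves.active_fl(l_norm))
    return params.f_iso_max * cos_alpha * f_len * VELOCITY_MULTIPLIER
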