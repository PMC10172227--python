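"""Gradient-based musculotendon parameter calibration from force observations.

Anatomical measurement alone cannot pin down the musculotendon parameters —
in particular the tendon-side parameter, which behaves as a phase shift of
the expressed force-length curve — so they must be calibrated against
kinetic data.  Given observations (l_mt, a, F_obs, weight), the loss

    L(theta) = mean_i[ w_i * (F(l_mt_i, a_i; theta) - F_obs_i)^2 ]

is minimized over a chosen free subset of {f_iso_max, l_opt_f, alpha_opt,
l_opt_mt} with the analytic partial derivatives supplying the exact
gradient.  The mean runs over observations while the weights stay
multiplicative, so rescaling all weights rescales the loss without moving
the minimizer.

Optimizer: scipy's bounded quasi-Newton (L-BFGS-B) on transformed
coordinates — positive parameters (forces, lengths) are log-transformed so
positivity is structural, the pennation angle is box-bounded in radians —
with gradients chain-ruled accordingly.  The tendon slack length is never a
free parameter itself: l_opt_mt is optimized and l_sla_t follows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .core import DegenerateFiberError, MuscleState, MusculotendonParams, muscle_force
from .curves import CharacteristicCurves
from .sensitivity import analytic_gradient

__all__ = [
    "ForceObservation",
    "CalibrationConfig",
    "CalibrationResult",
    "FREE_PARAMETER_IDS",
    "loss_and_gradient",
    "calibrate",
]

logger = logging.getLogger("mts.calibration")

FREE_PARAMETER_IDS = ("f_iso_max", "l_opt_f", "alpha_opt", "l_opt_mt")

#: minimum observation span in normalized fiber length below which the
#: information matrix is near-singular and results are flagged
MIN_LNORM_SPAN = 0.1


@dataclass(frozen=True)
class ForceObservation:
    """One kinetic data point: MTU length (m), activation, force (N)."""

    l_mt: float
    a: float
    f_obs: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.l_mt <= 0:
            raise ValueError("l_mt must be positive")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("activation must be in [0, 1]")
        if self.f_obs < 0:
            raise ValueError("f_obs must be nonnegative")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


@dataclass(frozen=True)
class CalibrationConfig:
    """Stopping rules and bound box for the bounded quasi-Newton fit."""

    max_iter: int = 200
    grad_tol: float = 1e-8  # projected-gradient norm for convergence
    #: multiplicative bound half-width for log-transformed parameters
    length_bound_factor: float = 3.0
    alpha_bounds_deg: Tuple[float, float] = (0.0, 45.0)
    #: normalized-sensitivity column norm below which a free parameter is
    #: reported unidentifiable from the data
    identifiability_tol: float = 1e-8


@dataclass
class CalibrationResult:
    """Outcome of a calibration run."""

    params: MusculotendonParams
    loss_trajectory: List[float]
    grad_norm: float
    converged: bool
    n_excluded: int
    bounds_hit: List[str]
    unidentifiable: List[str]
    warnings: List[str] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss_trajectory[-1]


def _set_param(params: MusculotendonParams, which: str, value: float):
    if which == "f_iso_max":
        return params.with_(f_iso_max=value, sigma_iso_max=None, volume=None)
    if which == "l_opt_f":
        return params.with_(l_opt_f=value, sigma_iso_max=None, volume=None)
    if which == "alpha_opt":
        return params.with_(alpha_opt=value)
    if which == "l_opt_mt":
        return params.with_(l_opt_mt=value)
    raise ValueError(f"unknown free parameter {which!r}")


def _apply(params: MusculotendonParams, free: Sequence[str], values) -> MusculotendonParams:
    for which, v in zip(free, values):
        params = _set_param(params, which, v)
    return params


def loss_and_gradient(
    params: MusculotendonParams,
    observations: Sequence[ForceObservation],
    free: Sequence[str],
    curves: CharacteristicCurves | None = None,
) -> Tuple[float, np.ndarray, int]:
    """Weighted mean squared force residual and its analytic gradient.

    Returns ``(loss, gradient, n_excluded)`` where the gradient is ordered
    as ``free`` and assembled from the closed-form partial derivatives
    (dF/dF_iso_max = F/F_iso_max).  Observations infeasible for the current
    parameters (degenerate fiber) are excluded with a warning and counted.
    """
    if not observations:
        raise ValueError("observations must be nonempty")
    bad = set(free) - set(FREE_PARAMETER_IDS)
    if bad:
        raise ValueError(f"unknown free parameters {sorted(bad)}")
    n = len(observations)
    loss = 0.0
    grad = np.zeros(len(free))
    n_excluded = 0
    for obs in observations:
        try:
            f_model = muscle_force(params, MuscleState(obs.l_mt, obs.a), curves)
            partials = [
                analytic_gradient(which, params, obs.l_mt, obs.a, curves)
                for which in free
            ]
        except DegenerateFiberError:
            n_excluded += 1
            logger.warning(
                "observation at l_mt=%g m infeasible for current parameters; excluded",
                obs.l_mt,
            )
            continue
        r = f_model - obs.f_obs
        loss += obs.weight * r * r / n
        for k, dF in enumerate(partials):
            grad[k] += 2.0 * obs.weight * r * dF / n
    return loss, grad, n_excluded


def _lnorm_span(params: MusculotendonParams, observations) -> float:
    lns = []
    for obs in observations:
        s = obs.l_mt - params.l_sla_t
        h = params.l_opt_f * math.sin(params.alpha_opt)
        if h == 0.0 and s <= 0.0:
            continue
        lns.append(math.hypot(s, h) / params.l_opt_f)
    return (max(lns) - min(lns)) if len(lns) >= 2 else 0.0


def calibrate(
    init: MusculotendonParams,
    observations: Sequence[ForceObservation],
    free: Sequence[str] = ("l_opt_f", "l_opt_mt"),
    bounds: Dict[str, Tuple[float, float]] | None = None,
    config: CalibrationConfig | None = None,
    curves: CharacteristicCurves | None = None,
) -> CalibrationResult:
    """Fit the free parameters to force observations by bounded quasi-Newton.

    Deterministic given inputs and config.  Positive parameters are
    optimized in log space; the pennation angle in radians with its box
    bound.  Default bounds place each positive parameter within
    ``length_bound_factor`` of its initial value.  Hitting the iteration cap
    returns a non-converged result rather than raising.
    """
    if config is None:
        config = CalibrationConfig()
    free = list(free)
    loss0, grad0, _ = loss_and_gradient(init, observations, free, curves)
    if not math.isfinite(loss0):
        raise ValueError("non-finite loss at the initial parameters")

    warnings_: List[str] = []
    span = _lnorm_span(init, observations)
    if span < MIN_LNORM_SPAN:
        warnings_.append(
            f"observations span only {span:.3f} in normalized fiber length "
            f"(< {MIN_LNORM_SPAN}); information matrix near-singular"
        )

    alpha_lo, alpha_hi = (math.radians(d) for d in config.alpha_bounds_deg)

    # transform: z = log(theta) for positive parameters, z = alpha for angle
    def to_z(which: str, theta: float) -> float:
        return theta if which == "alpha_opt" else math.log(theta)

    def from_z(which: str, z: float) -> float:
        return z if which == "alpha_opt" else math.exp(z)

    z0 = np.array([to_z(w, _get(init, w)) for w in free])
    z_bounds = []
    for w in free:
        if bounds and w in bounds:
            lo, hi = bounds[w]
        elif w == "alpha_opt":
            lo, hi = alpha_lo, alpha_hi
        else:
            theta0 = _get(init, w)
            lo, hi = theta0 / config.length_bound_factor, theta0 * config.length_bound_factor
        if w == "alpha_opt":
            z_bounds.append((max(lo, alpha_lo), min(hi, alpha_hi)))
        else:
            z_bounds.append((math.log(lo), math.log(hi)))

    track: List[float] = [loss0]
    # smooth finite penalty outside the feasible region (l_opt_mt must
    # exceed the projected fiber length); keeps the line search informed
    # where the force model is undefined
    min_slack = 1e-6 * init.l_opt_mt
    penalty_base = 10.0 * (loss0 + 1.0)

    def objective(z):
        theta = {w: from_z(w, zi) for w, zi in zip(free, z)}
        lf = theta.get("l_opt_f", init.l_opt_f)
        alpha = theta.get("alpha_opt", init.alpha_opt)
        l_mt_o = theta.get("l_opt_mt", init.l_opt_mt)
        slack = l_mt_o - lf * math.cos(alpha)
        if slack <= min_slack:
            v = (min_slack - slack) / init.l_opt_mt
            loss = penalty_base * (1.0 + v)
            dv = {  # d(loss)/dtheta of the penalty
                "l_opt_f": penalty_base * math.cos(alpha) / init.l_opt_mt,
                "alpha_opt": -penalty_base * lf * math.sin(alpha) / init.l_opt_mt,
                "l_opt_mt": -penalty_base / init.l_opt_mt,
                "f_iso_max": 0.0,
            }
            gz = np.array(
                [
                    dv[w] if w == "alpha_opt" else dv[w] * theta[w]
                    for w in free
                ]
            )
            return loss, gz
        p = _apply(init, free, [theta[w] for w in free])
        loss, grad, _ = loss_and_gradient(p, observations, free, curves)
        # chain rule: dL/dz = dL/dtheta * theta for log-transformed entries
        gz = np.array(
            [
                g if w == "alpha_opt" else g * from_z(w, zi)
                for w, zi, g in zip(free, z, grad)
            ]
        )
        return loss, gz

    res = minimize(
        objective,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=z_bounds,
        callback=lambda zk: track.append(objective(zk)[0]),
        options={"maxiter": config.max_iter, "gtol": config.grad_tol, "ftol": 1e-15},
    )
    # monotone-descent contract: keep the better of init and optimizer exit
    z_best = res.x if res.fun <= loss0 else z0
    fitted = _apply(init, free, [from_z(w, zi) for w, zi in zip(free, z_best)])
    loss_f, _, n_excl = loss_and_gradient(fitted, observations, free, curves)
    track.append(loss_f)
    grad_norm = float(np.linalg.norm(objective(z_best)[1]))

    bounds_hit = [
        w
        for w, zi, (lo, hi) in zip(free, z_best, z_bounds)
        if math.isclose(zi, lo, abs_tol=1e-12) or math.isclose(zi, hi, abs_tol=1e-12)
    ]

    # flat-gradient identifiability diagnostic: per-parameter normalized
    # sensitivity of the model over the data
    unident: List[str] = []
    for which in free:
        theta = _get(fitted, which)
        col = 0.0
        for obs in observations:
            try:
                dF = analytic_gradient(which, fitted, obs.l_mt, obs.a, curves)
            except DegenerateFiberError:
                continue
            scale = theta if which != "alpha_opt" else max(theta, 1.0)
            col += (dF * scale / fitted.f_iso_max) ** 2
        if math.sqrt(col) < config.identifiability_tol:
            unident.append(which)
            warnings_.append(
                f"{which}: flat gradient over the observations; parameter "
                "unidentifiable from these data"
            )

    converged = bool(res.success) or grad_norm < config.grad_tol
    return CalibrationResult(
        params=fitted,
        loss_trajectory=track,
        grad_norm=grad_norm,
        converged=converged,
        n_excluded=n_excl,
        bounds_hit=bounds_hit,
        unidentifiable=unident,
        warnings=warnings_,
    )


def _get(params: MusculotendonParams, which: str) -> float:
    return {
        "f_iso_max": params.f_iso_max,
        "l_opt_f": params.l_opt_f,
        "alpha_opt": params.alpha_opt,
        "l_opt_mt": params.l_opt_mt,
    }[which]
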