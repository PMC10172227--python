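"""Synthetic architecture tables and force observations with known truth.

The generator emulates the value ranges of lower-limb muscle architecture
datasets: raw sarcomere lengths 2.0-3.2 um, pennation 0-30 degrees, fiber
lengths of a few to ~12 cm, volumes up to ~900 cm^3 and specific tensions
in the 25-61 N/cm^2 range seen across the literature.  Ground-truth optimal
parameters are drawn first and the raw measurements constructed by
*inverse* scaling (raw fiber length = optimal * l_s_raw/l_s_opt, raw
pennation from the constant-thickness relation), so running the derivation
pipeline on the synthetic records must recover the truth exactly — an
end-to-end oracle for the whole derivation path.

Force observations are model forces with seeded mean-zero multiplicative
noise of a chosen coefficient of variation, for calibration recovery
experiments.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np

from .calibration import ForceObservation
from .core import MuscleState, MusculotendonParams, muscle_force
from .curves import CharacteristicCurves
from .derivation import ArchitectureRecord
from .sensitivity import mtu_length_at_lnorm

__all__ = ["synth_architecture", "synth_force_observations"]

_L_S_OPT_UM = 2.7


def synth_architecture(
    n_muscles: int, seed: int
) -> Tuple[List[ArchitectureRecord], List[MusculotendonParams]]:
    """Generate raw architecture records plus their hidden ground truth.

    Deterministic per seed.  Returns ``(records, truth)`` where
    ``truth[i]`` is the parameter set that derivation with the default
    config (optimal sarcomere 2.7 um, scaling on) recovers from
    ``records[i]``.
    """
    if n_muscles < 1:
        raise ValueError("n_muscles must be >= 1")
    rng = np.random.default_rng(seed)
    records, truth = [], []
    for i in range(n_muscles):
        l_opt_f = rng.uniform(0.04, 0.12)  # m
        alpha_opt = math.radians(rng.uniform(0.0, 30.0))
        l_s_raw = rng.uniform(2.0, 3.2)  # um
        volume = rng.uniform(100.0, 900.0)  # cm^3
        sigma = rng.uniform(25.0, 61.0)  # N/cm^2
        ratio = rng.uniform(3.0, 10.0)  # l_opt_mt / l_opt_f
        l_opt_mt = ratio * l_opt_f

        # inverse optimal scaling: what the fixation-position measurement
        # would have been for this ground truth
        l_f_raw_mm = l_opt_f * 1000.0 * l_s_raw / _L_S_OPT_UM
        sin_meas = _L_S_OPT_UM * math.sin(alpha_opt) / l_s_raw
        alpha_raw_deg = math.degrees(math.asin(sin_meas))

        f_iso_max = sigma * volume / (l_opt_f * 100.0)
        truth.append(
            MusculotendonParams(
                f_iso_max=f_iso_max,
                l_opt_f=l_opt_f,
                alpha_opt=alpha_opt,
                l_opt_mt=l_opt_mt,
                sigma_iso_max=sigma,
                volume=volume,
                name=f"synth_{i:02d}",
            )
        )
        records.append(
            ArchitectureRecord(
                muscle=f"synth_{i:02d}",
                fiber_length_mm=l_f_raw_mm,
                sarcomere_length_um=l_s_raw,
                pennation_deg=alpha_raw_deg,
                volume_cm3=volume,
                mtu_length_opt_mm=l_opt_mt * 1000.0,
                specific_tension_ncm2=sigma,
            )
        )
    return records, truth


def synth_force_observations(
    params: MusculotendonParams,
    l_norm_range: Tuple[float, float] = (0.5, 1.4),
    n: int = 50,
    noise_cv: float = 0.0,
    seed: int = 0,
    a: float = 1.0,
    curves: CharacteristicCurves | None = None,
) -> List[ForceObservation]:
    """Noisy isometric force observations on an even normalized-length grid.

    F_obs = F_model * (1 + eta) with eta ~ Normal(0, noise_cv), seeded;
    exactly on the model curve when ``noise_cv`` is 0.  Forces are floored
    at zero (observed forces are magnitudes).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = l_norm_range
    sin_a = math.sin(params.alpha_opt)
    if lo < sin_a:
        raise ValueError(
            f"l_norm range start {lo} below sin(alpha_opt)={sin_a:.3f}: infeasible"
        )
    rng = np.random.default_rng(seed)
    l_norms = np.linspace(lo, hi, n)
    l_mts = mtu_length_at_lnorm(params, l_norms)
    out = []
    for lmt in l_mts:
        f = muscle_force(params, MuscleState(float(lmt), a), curves)
        if noise_cv > 0.0:
            f *= 1.0 + rng.normal(0.0, noise_cv)
        out.append(ForceObservation(l_mt=float(lmt), a=a, f_obs=max(f, 0.0)))
    return out
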