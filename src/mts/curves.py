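"""Hill-type characteristic force-length curves.

The contraction-dynamics equation multiplies maximal isometric force by a
dimensionless curve factor built from the active and passive force-length
curves, both functions of normalized fiber length.  The curves here are
pluggable: any object exposing ``active_fl``, ``passive_fl`` and their first
derivatives with the invariants below can be injected into the force and
sensitivity routines.

Default shapes
--------------
active   f_ce(l) = exp(-(l - 1)^2 / gamma),  gamma = 0.45
passive  f_pe(l) = 0 for l <= 1 + slack_strain, else
         (exp(k*x) - 1 - k*x - (k*x)^2/2) / (exp(k) - 1 - k - k^2/2)
         with x = (l - 1 - slack_strain) / (strain_max - slack_strain)

The passive anchors follow the common Millard-style defaults: passive force
begins to develop at strain 0 and reaches the maximal isometric value at
strain 0.7.  Subtracting the linear and quadratic Taylor terms makes the
curve C2 at the slack point (value, slope and curvature all vanish from
both sides), so every force derivative taken through it is smooth and
two-sided — a requirement for the central finite-difference oracle checks
of the sensitivity analysis, including at the optimal length itself.  Invariants: f_ce(1) = 1 with zero
slope (peak at optimal length), f_ce >= 0, f_pe = 0 below slack,
nondecreasing, and f_pe(1 + strain_max) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CharacteristicCurves", "default_curves"]


@dataclass(frozen=True)
class CharacteristicCurves:
    """Active/passive force-length curves with analytic first derivatives.

    Parameters
    ----------
    gamma
        Width of the Gaussian active curve (dimensionless, in squared
        normalized-length units).  Larger gamma -> wider plateau.
    slack_strain
        Normalized-fiber strain at which passive force starts (default 0).
    strain_max
        Strain at which passive force equals the maximal isometric value
        (default 0.7).
    k_passive
        Exponential shape factor of the passive curve (default 4).
    """

    gamma: float = 0.45
    slack_strain: float = 0.0
    strain_max: float = 0.7
    k_passive: float = 4.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not self.strain_max > self.slack_strain >= 0:
            raise ValueError("need strain_max > slack_strain >= 0")
        if self.k_passive <= 0:
            raise ValueError("k_passive must be positive")

    # -- active -----------------------------------------------------------
    def active_fl(self, l_norm):
        """Active force-length multiplier f_ce(l_norm), peak-normalized."""
        l = np.asarray(l_norm, dtype=float)
        return np.exp(-((l - 1.0) ** 2) / self.gamma)

    def d_active_fl(self, l_norm):
        """d f_ce / d l_norm."""
        l = np.asarray(l_norm, dtype=float)
        return -2.0 * (l - 1.0) / self.gamma * np.exp(-((l - 1.0) ** 2) / self.gamma)

    # -- passive ----------------------------------------------------------
    @property
    def _e_span(self) -> float:
        return self.strain_max - self.slack_strain

    def passive_fl(self, l_norm):
        """Passive force-length multiplier f_pe(l_norm); 0 below slack, C2."""
        l = np.asarray(l_norm, dtype=float)
        k = self.k_passive
        x = (l - 1.0 - self.slack_strain) / self._e_span
        kx = k * x
        norm = np.expm1(k) - k - 0.5 * k * k
        val = (np.expm1(kx) - kx - 0.5 * kx * kx) / norm
        return np.where(x > 0.0, val, 0.0)

    def d_passive_fl(self, l_norm):
        """d f_pe / d l_norm (C1, vanishing at the slack point)."""
        l = np.asarray(l_norm, dtype=float)
        k = self.k_passive
        x = (l - 1.0 - self.slack_strain) / self._e_span
        kx = k * x
        norm = np.expm1(k) - k - 0.5 * k * k
        slope = k / self._e_span * (np.expm1(kx) - kx) / norm
        return np.where(x > 0.0, slope, 0.0)


def default_curves() -> CharacteristicCurves:
    """Default curve set used throughout when none is supplied."""
    return CharacteristicCurves()
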