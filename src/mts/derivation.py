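"""Derive musculotendon parameters from raw muscle-architecture measurements.

Raw cadaveric or imaging measurements (fiber length, sarcomere length,
pennation angle, muscle volume) are anatomical quantities taken at whatever
joint position the specimen was fixed in; the Hill-type model instead needs
the values at the fiber's *optimal* state (maximal active isometric force).
This module makes each conversion step explicit:

* optimal scaling of fiber length by the sarcomere-length ratio,
* optimal scaling of pennation angle under constant muscle thickness,
* PCSA from volume and optimal fiber length (conventional or projected),
* maximal isometric force from specific tension and PCSA,
* tendon slack length from the MTU length at the optimal joint position,

and :func:`derive_dataset` composes them per muscle with a derivation log
recording every applied or omitted step, so that downstream provenance
auditing can see exactly which simplifications a parameter set carries.

Angles are degrees and lengths mm/um at this boundary, matching how the
architecture datasets report them; the derived parameter set is SI.
"""

from __future__ import annotations

import math
from typing import List, Literal, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import MusculotendonParams, tendon_slack_length

__all__ = [
    "ArchitectureRecord",
    "DerivationConfig",
    "DerivationError",
    "scale_fiber_length",
    "scale_pennation",
    "pcsa_conventional",
    "pcsa_projected",
    "max_isometric_force",
    "rescale_specific_tension",
    "tendon_slack_length",
    "derive_dataset",
]


class DerivationError(ValueError):
    """A derivation step received inputs outside its domain."""


class ArchitectureRecord(BaseModel):
    """One muscle's raw architecture measurements (dataset units).

    Optional fields are ``None`` when the dataset does not report them;
    they are never silently defaulted.
    """

    model_config = ConfigDict(frozen=True)

    muscle: str
    fiber_length_mm: float = Field(gt=0)
    pennation_deg: float = Field(ge=0, lt=90)
    sarcomere_length_um: Optional[float] = Field(default=None, gt=0)
    volume_cm3: Optional[float] = Field(default=None, gt=0)
    pcsa_cm2: Optional[float] = Field(default=None, gt=0)
    pcsa_kind: Optional[Literal["conventional", "projected"]] = None
    mtu_length_opt_mm: Optional[float] = Field(default=None, gt=0)
    specific_tension_ncm2: Optional[float] = Field(default=None, gt=0)
    tendon_slack_mm: Optional[float] = Field(default=None, gt=0)
    provenance: Optional[str] = None

    @model_validator(mode="after")
    def _sanity(self) -> "ArchitectureRecord":
        s = self.sarcomere_length_um
        if s is not None and not 1.0 <= s <= 5.0:
            raise ValueError(
                f"sarcomere_length_um={s} outside the 1.0-5.0 um sanity range"
            )
        if self.pcsa_cm2 is not None and self.pcsa_kind is None:
            raise ValueError("pcsa_cm2 given without pcsa_kind")
        return self


class DerivationConfig(BaseModel):
    """Options controlling the raw-measurement -> parameter pipeline."""

    model_config = ConfigDict(frozen=True)

    l_s_opt_um: float = Field(default=2.7, ge=2.2, le=3.2)
    pcsa_mode: Literal["conventional", "projected"] = "conventional"
    pennation_scaling: bool = True
    #: use the raw (unscaled) pennation angle in projected PCSA, reproducing
    #: the legacy fixed-pennation-angle behavior for auditing
    legacy_fixed_pennation_pcsa: bool = False
    tendon_mode: Literal["from_optimal_position", "measured"] = "from_optimal_position"
    round_decimals: Optional[int] = None


# ---------------------------------------------------------------------------
# elementary derivation steps


def scale_fiber_length(l_f_raw: float, l_s_raw: float, l_s_opt: float) -> float:
    """Optimal scaling of fiber length by the sarcomere-length ratio.

    Fibers are sarcomeres in series, so fiber length scales linearly with
    sarcomere length: returns ``l_f_raw * l_s_opt / l_s_raw``.
    """
    if l_f_raw <= 0 or l_s_raw <= 0 or l_s_opt <= 0:
        raise DerivationError("scale_fiber_length requires positive inputs")
    return l_f_raw * l_s_opt / l_s_raw


def scale_pennation(alpha_meas_deg: float, l_s_meas: float, l_s_opt: float) -> float:
    """Optimal scaling of pennation angle (degrees in, degrees out).

    Under constant muscle thickness, fiber * sin(alpha) is invariant, and
    fiber length tracks sarcomere length, so
    alpha_opt = asin(l_s_meas * sin(alpha_meas) / l_s_opt).
    """
    if not 0.0 <= alpha_meas_deg < 90.0:
        raise DerivationError("alpha_meas must be in [0, 90) degrees")
    if l_s_meas <= 0 or l_s_opt <= 0:
        raise DerivationError("sarcomere lengths must be positive")
    x = l_s_meas * math.sin(math.radians(alpha_meas_deg)) / l_s_opt
    if x > 1.0:
        raise DerivationError(
            "constant-thickness model violated: "
            f"l_s_meas*sin(alpha)/l_s_opt = {x:g} > 1"
        )
    return math.degrees(math.asin(x))


def pcsa_conventional(volume: float, l_opt_f: float) -> float:
    """Conventional PCSA = volume / optimal fiber length (cm^3 / cm -> cm^2)."""
    if volume <= 0 or l_opt_f <= 0:
        raise DerivationError("pcsa_conventional requires positive inputs")
    return volume / l_opt_f


def pcsa_projected(volume: float, l_opt_f: float, alpha_opt_deg: float) -> float:
    """Projected (functional) PCSA = (V / l_opt_f) * cos(alpha_opt).

    Close to the anatomical cross-sectional area; the cosine projects the
    fiber cross-section onto the tendon line of action.
    """
    if not 0.0 <= alpha_opt_deg < 90.0:
        raise DerivationError("alpha_opt must be in [0, 90) degrees")
    return pcsa_conventional(volume, l_opt_f) * math.cos(math.radians(alpha_opt_deg))


def max_isometric_force(sigma: float, pcsa: float) -> float:
    """Maximal isometric force = specific tension * PCSA (N/cm^2 * cm^2 -> N)."""
    if sigma <= 0 or pcsa <= 0:
        raise DerivationError("max_isometric_force requires positive inputs")
    return sigma * pcsa


def rescale_specific_tension(sigma: float, l_s_ratio: float) -> float:
    """Specific tension consistent with sarcomere-rescaled fiber lengths.

    If optimal fiber lengths are scaled up by ``l_s_ratio``, PCSA = V/l
    shrinks by the same ratio; the specific tension that preserves
    F_iso_max is therefore ``sigma * l_s_ratio``.
    """
    if sigma <= 0 or l_s_ratio <= 0:
        raise DerivationError("rescale_specific_tension requires positive inputs")
    return sigma * l_s_ratio


# ---------------------------------------------------------------------------
# dataset pipeline

_MM = 1e-3  # mm -> m


def _derive_one(
    rec: ArchitectureRecord, config: DerivationConfig
) -> Tuple[MusculotendonParams, List[str]]:
    log: List[str] = []
    l_s_opt = config.l_s_opt_um

    # optimal fiber length
    if rec.sarcomere_length_um is not None:
        l_opt_f_mm = scale_fiber_length(
            rec.fiber_length_mm, rec.sarcomere_length_um, l_s_opt
        )
        log.append(
            f"fiber scaled: {rec.fiber_length_mm:g} mm * {l_s_opt:g}/"
            f"{rec.sarcomere_length_um:g} = {l_opt_f_mm:g} mm"
        )
    else:
        l_opt_f_mm = rec.fiber_length_mm
        log.append(
            "optimal-at-rest simplification: no sarcomere length, raw fiber "
            "length used as optimal"
        )

    # optimal pennation angle
    if rec.sarcomere_length_um is not None and config.pennation_scaling:
        alpha_opt_deg = scale_pennation(
            rec.pennation_deg, rec.sarcomere_length_um, l_s_opt
        )
        log.append(
            f"pennation scaled: {rec.pennation_deg:g} deg -> {alpha_opt_deg:g} deg"
        )
    else:
        alpha_opt_deg = rec.pennation_deg
        if config.pennation_scaling and rec.sarcomere_length_um is None:
            log.append(
                "optimal-at-rest simplification: no sarcomere length, raw "
                "pennation used as optimal"
            )
        else:
            log.append("pennation scaling off: raw pennation used as optimal")

    # PCSA
    pcsa: Optional[float] = None
    if rec.volume_cm3 is not None:
        if config.pcsa_mode == "projected":
            alpha_for_pcsa = (
                rec.pennation_deg
                if config.legacy_fixed_pennation_pcsa
                else alpha_opt_deg
            )
            pcsa = pcsa_projected(rec.volume_cm3, l_opt_f_mm / 10.0, alpha_for_pcsa)
            if config.legacy_fixed_pennation_pcsa:
                log.append(
                    "fixed-pennation-angle simplification: raw pennation used "
                    "in projected PCSA"
                )
            log.append(f"projected PCSA from volume: {pcsa:g} cm^2")
        else:
            pcsa = pcsa_conventional(rec.volume_cm3, l_opt_f_mm / 10.0)
            log.append(f"conventional PCSA from volume: {pcsa:g} cm^2")
        if rec.pcsa_cm2 is not None:
            rel = abs(pcsa - rec.pcsa_cm2) / rec.pcsa_cm2
            log.append(
                f"reported PCSA {rec.pcsa_cm2:g} cm^2 ({rec.pcsa_kind}) "
                f"superseded by volume-based value (discrepancy {rel:.1%})"
            )
    elif rec.pcsa_cm2 is not None:
        pcsa = rec.pcsa_cm2
        log.append(f"reported {rec.pcsa_kind} PCSA used as-is: {pcsa:g} cm^2")
    else:
        raise DerivationError(
            f"{rec.muscle}: neither volume_cm3 nor pcsa_cm2 available"
        )

    if rec.specific_tension_ncm2 is None:
        raise DerivationError(f"{rec.muscle}: specific_tension_ncm2 missing")
    f_iso_max = max_isometric_force(rec.specific_tension_ncm2, pcsa)
    log.append(
        f"F_iso_max = {rec.specific_tension_ncm2:g} N/cm^2 * {pcsa:g} cm^2 "
        f"= {f_iso_max:g} N"
    )

    # tendon side: MTU length at the optimal joint position
    if config.tendon_mode == "measured":
        if rec.tendon_slack_mm is None:
            raise DerivationError(
                f"{rec.muscle}: tendon_mode='measured' but tendon_slack_mm missing"
            )
        l_opt_mt_mm = rec.tendon_slack_mm + l_opt_f_mm * math.cos(
            math.radians(alpha_opt_deg)
        )
        log.append(
            "slack-at-rest simplification: measured tendon length "
            f"{rec.tendon_slack_mm:g} mm used directly as slack length"
        )
    else:
        if rec.mtu_length_opt_mm is None:
            raise DerivationError(f"{rec.muscle}: mtu_length_opt_mm missing")
        l_opt_mt_mm = rec.mtu_length_opt_mm
        l_sla_mm = tendon_slack_length(
            l_opt_mt_mm * _MM, l_opt_f_mm * _MM, math.radians(alpha_opt_deg)
        ) / _MM
        log.append(
            f"tendon slack length from optimal MTU length: {l_sla_mm:g} mm"
        )

    # carry sigma/volume only when F_iso_max is volume-derived, so the
    # volume-coupled force sensitivity stays available downstream
    sigma = volume = None
    if rec.volume_cm3 is not None and config.pcsa_mode == "conventional":
        sigma, volume = rec.specific_tension_ncm2, rec.volume_cm3

    params = MusculotendonParams(
        f_iso_max=f_iso_max,
        l_opt_f=l_opt_f_mm * _MM,
        alpha_opt=math.radians(alpha_opt_deg),
        l_opt_mt=l_opt_mt_mm * _MM,
        sigma_iso_max=sigma,
        volume=volume,
        name=rec.muscle,
    )
    return params, log


def derive_dataset(
    records: List[ArchitectureRecord], config: DerivationConfig | None = None
) -> Tuple[pd.DataFrame, dict]:
    """Derive one parameter row per muscle plus a per-muscle derivation log.

    Returns ``(table, logs)``.  ``table`` has SI columns (f_iso_max_n,
    l_opt_f_m, alpha_opt_rad, l_opt_mt_m, l_sla_t_m, plus sigma/volume when
    volume-derived); ``logs`` maps muscle name to its list of log lines, with
    a special ``"__errors__"`` entry collecting per-record validation
    failures instead of dropping them silently.
    """
    if config is None:
        config = DerivationConfig()
    rows, logs, errors = [], {}, []
    for rec in records:
        try:
            params, log = _derive_one(rec, config)
        except (DerivationError, ValueError) as exc:
            errors.append(f"{rec.muscle}: {exc}")
            continue
        logs[rec.muscle] = log
        rows.append(
            {
                "muscle": params.name,
                "f_iso_max_n": params.f_iso_max,
                "l_opt_f_m": params.l_opt_f,
                "alpha_opt_rad": params.alpha_opt,
                "l_opt_mt_m": params.l_opt_mt,
                "l_sla_t_m": params.l_sla_t,
                "sigma_iso_max_ncm2": params.sigma_iso_max,
                "volume_cm3": params.volume,
            }
        )
    table = pd.DataFrame(rows)
    if config.round_decimals is not None and not table.empty:
        num = table.select_dtypes("number").columns
        table[num] = table[num].round(config.round_decimals)
    logs["__errors__"] = errors
    return table, logs
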