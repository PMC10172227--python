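"""File formats: architecture CSV, parameter JSON, observation CSV.

Boundary conventions: CSV is UTF-8, comma-separated, '.' decimal, header
row mandatory; angles in degrees and lengths in mm/um at file boundaries
(matching how architecture datasets report them), SI internally.  Every
numeric output file carries a header comment with the tool version, the
seed, and a hash of the configuration that produced it.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd
from pydantic import ValidationError

from . import __version__
from .core import MusculotendonParams, tendon_slack_length
from .curves import CharacteristicCurves
from .derivation import ArchitectureRecord

__all__ = [
    "ARCHITECTURE_COLUMNS",
    "read_architecture_csv",
    "write_architecture_csv",
    "read_observations_csv",
    "write_observations_csv",
    "save_params_json",
    "load_params_json",
    "write_table",
    "config_hash",
]

#: mandatory architecture CSV header (optional extras like tendon_slack_mm
#: may follow)
ARCHITECTURE_COLUMNS = [
    "muscle",
    "fiber_length_mm",
    "sarcomere_length_um",
    "pennation_deg",
    "volume_cm3",
    "pcsa_cm2",
    "pcsa_kind",
    "mtu_length_opt_mm",
    "specific_tension_ncm2",
]

_FLOAT_COLUMNS = {c for c in ARCHITECTURE_COLUMNS if c not in ("muscle", "pcsa_kind")}
_FLOAT_COLUMNS.add("tendon_slack_mm")

_SLACK_LOAD_RTOL = 1e-6


def config_hash(config: object) -> str:
    """Short stable hash of a configuration mapping/dataclass for headers."""
    if hasattr(config, "model_dump"):
        config = config.model_dump()
    elif hasattr(config, "__dict__"):
        config = dict(vars(config))
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:10]


def _header_comment(seed: Optional[int], config: object) -> str:
    return (
        f"# mts v{__version__} seed={seed if seed is not None else 'none'} "
        f"config={config_hash(config or {})}"
    )


def write_table(
    df: pd.DataFrame, path, seed: Optional[int] = None, config: object = None
) -> None:
    """Write a DataFrame as CSV with the provenance header comment."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(seed, config) + "\n")
        df.to_csv(fh, index=False)


def read_architecture_csv(path) -> List[ArchitectureRecord]:
    """Read raw architecture measurements; typed, with row-level errors.

    Empty optional cells load as absent (None), never as zero.  A malformed
    header or cell raises with the offending column/row named.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    missing = [c for c in ARCHITECTURE_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: header missing columns {missing}")
    records: List[ArchitectureRecord] = []
    for i, row in enumerate(rows[1:], start=2):
        cells = dict(zip(header, (c.strip() for c in row)))
        kwargs = {}
        for col, raw in cells.items():
            if col not in _FLOAT_COLUMNS and col not in ("muscle", "pcsa_kind"):
                continue
            if raw == "":
                continue
            if col in _FLOAT_COLUMNS:
                try:
                    kwargs[col] = float(raw)
                except ValueError:
                    raise ValueError(
                        f"{path}:{i}: cannot parse {col}={raw!r} as a number"
                    ) from None
            else:
                kwargs[col] = raw
        try:
            records.append(ArchitectureRecord(**kwargs))
        except ValidationError as exc:
            raise ValueError(f"{path}:{i}: {exc}") from None
    return records


def write_architecture_csv(
    records: List[ArchitectureRecord], path, seed: Optional[int] = None, config=None
) -> None:
    rows = []
    for r in records:
        d = r.model_dump(exclude={"provenance"})
        rows.append({k: ("" if v is None else v) for k, v in d.items()})
    df = pd.DataFrame(rows, columns=ARCHITECTURE_COLUMNS + ["tendon_slack_mm"])
    write_table(df, path, seed=seed, config=config)


# ---------------------------------------------------------------------------
# force observations (calibration data)

OBSERVATION_COLUMNS = ["mtu_length_m", "activation", "force_n"]


def read_observations_csv(path):
    """Read observations (mtu_length_m, activation, force_n[, weight])."""
    from .calibration import ForceObservation

    df = pd.read_csv(path, comment="#")
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header missing columns {missing}")
    weights = df["weight"] if "weight" in df.columns else [1.0] * len(df)
    return [
        ForceObservation(l_mt=l, a=a, f_obs=f, weight=w)
        for l, a, f, w in zip(
            df["mtu_length_m"], df["activation"], df["force_n"], weights
        )
    ]


def write_observations_csv(observations, path, seed=None, config=None) -> None:
    df = pd.DataFrame(
        {
            "mtu_length_m": [o.l_mt for o in observations],
            "activation": [o.a for o in observations],
            "force_n": [o.f_obs for o in observations],
            "weight": [o.weight for o in observations],
        }
    )
    write_table(df, path, seed=seed, config=config)


# ---------------------------------------------------------------------------
# parameter sets (JSON)


def save_params_json(
    params: MusculotendonParams, path, curves: CharacteristicCurves | None = None
) -> None:
    """Serialize a parameter set (and curve shape) to JSON.

    Angles are stored in degrees at this boundary; the redundant l_sla_t_m
    is written for human inspection and cross-checked on load.
    """
    doc = {
        "name": params.name,
        "f_iso_max_N": params.f_iso_max,
        "l_opt_f_m": params.l_opt_f,
        "alpha_opt_deg": math.degrees(params.alpha_opt),
        "l_opt_mt_m": params.l_opt_mt,
        "l_sla_t_m": params.l_sla_t,
    }
    if params.sigma_iso_max is not None:
        doc["sigma_iso_max_Ncm2"] = params.sigma_iso_max
        doc["volume_cm3"] = params.volume
    if curves is not None:
        doc["curve"] = {
            "gamma": curves.gamma,
            "k_passive": curves.k_passive,
            "strain_max": curves.strain_max,
            "slack_strain": curves.slack_strain,
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_params_json(path) -> Tuple[MusculotendonParams, CharacteristicCurves]:
    """Load a parameter set; the slack length is recomputed, not trusted.

    l_sla_t is re-derived from l_opt_mt - l_opt_f*cos(alpha_opt); a stored
    value differing by more than 1e-6 relative is an error (the file is
    internally inconsistent).
    """
    with open(path) as fh:
        doc = json.load(fh)
    alpha = math.radians(doc["alpha_opt_deg"])
    params = MusculotendonParams(
        f_iso_max=doc["f_iso_max_N"],
        l_opt_f=doc["l_opt_f_m"],
        alpha_opt=alpha,
        l_opt_mt=doc["l_opt_mt_m"],
        sigma_iso_max=doc.get("sigma_iso_max_Ncm2"),
        volume=doc.get("volume_cm3"),
        name=doc.get("name", ""),
    )
    if "l_sla_t_m" in doc:
        recomputed = tendon_slack_length(params.l_opt_mt, params.l_opt_f, alpha)
        if abs(recomputed - doc["l_sla_t_m"]) > _SLACK_LOAD_RTOL * recomputed:
            raise ValueError(
                f"{path}: stored l_sla_t_m={doc['l_sla_t_m']:g} inconsistent "
                f"with recomputed {recomputed:g}"
            )
    cdoc = doc.get("curve") or {}
    curves = CharacteristicCurves(
        gamma=cdoc.get("gamma", 0.45),
        k_passive=cdoc.get("k_passive", 4.0),
        strain_max=cdoc.get("strain_max", 0.7),
        slack_strain=cdoc.get("slack_strain", 0.0),
    )
    return params, curves
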