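"""Machine-checkable audit of musculotendon parameter-derivation provenance.

Muscle architecture datasets and the models built on them routinely carry
simplifications: raw fixation-position measurements used as optimal values,
quantities mixed across subject cohorts, tendon lengths taken at rest.
This module encodes nine such simplifications as deterministic rules over
explicit provenance metadata, each graded for uncertainty (how far the
derived value may sit from its definition) and for impact on muscle force
estimation.  The verbal qualifiers behind the grades ("large pennation",
"sarcomere much different from optimal") are quantified with explicit,
configurable thresholds that are echoed in every report.

Scope: the report reflects potential uncertainty in the contraction
dynamics only; it must not be read as a judgment of overall simulation
accuracy, which also hinges on musculoskeletal geometry and other model
components outside this audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "SIMPLIFICATIONS",
    "ProvenanceMetadata",
    "AuditThresholds",
    "Finding",
    "AuditReport",
    "grade_thresholds",
    "audit",
    "load_metadata_yaml",
]

#: The closed set of simplification names a finding can carry.
#: optimal_at_rest appears once per affected parameter, as distinct findings.
SIMPLIFICATIONS = (
    "optimal_at_rest_fiber_length",
    "uniform_optimal_sarcomere_length",
    "fixed_pennation_angle",
    "inherited_fiber_length",
    "inherited_specific_tension",
    "uniform_specific_tension",
    "optimal_at_rest_pennation",
    "optimal_at_rest_tendon",
    "slack_at_rest",
)

Uncertainty = Literal["small", "considerable", "large"]
Impact = Literal["neglectable", "considerable", "severe"]


class ProvenanceMetadata(BaseModel):
    """How a parameter set was produced, per muscle or per dataset.

    Booleans are mandatory — an audit must not guess defaults — and labels
    come from closed vocabularies so rule evaluation is unambiguous.
    """

    model_config = ConfigDict(frozen=True)

    name: str = "unnamed"
    sarcomere_measured: bool
    fiber_scaled_to_optimal: bool
    uniform_optimal_sarcomere: bool
    pennation_scaled: bool
    pennation_raw_used_in_projected_pcsa: bool
    fiber_length_source_cohort: str
    volume_source_cohort: str
    specific_tension_source: Literal["same_cohort", "inherited", "uniform"]
    tendon_mode: Literal[
        "computed_at_measurement_position",
        "computed_at_calibrated_position",
        "measured_length",
    ]
    raw_pennation_deg: Optional[float] = Field(default=None, ge=0, lt=90)
    raw_sarcomere_um: Optional[float] = Field(default=None, gt=0)


class AuditThresholds(BaseModel):
    """Quantified cutoffs behind the verbal grade qualifiers."""

    model_config = ConfigDict(frozen=True)

    #: pennation counted "large" above this (cosine leaves the small-angle
    #: regime beyond ~20 degrees)
    large_pennation_deg: float = 20.0
    #: sarcomere counted "much different from optimal" beyond this relative
    #: deviation of l_s_opt from the raw value
    sarcomere_deviation: float = 0.10
    l_s_opt_um: float = 2.7


@dataclass(frozen=True)
class GradeInputs:
    """Boolean qualifiers feeding the grade escalation rules."""

    large_pennation: Optional[bool]
    sarcomere_far_from_optimal: Optional[bool]
    thresholds: AuditThresholds


def grade_thresholds(
    metadata: ProvenanceMetadata, thresholds: AuditThresholds | None = None
) -> GradeInputs:
    """Evaluate the quantified qualifiers for one metadata record.

    A qualifier is None when the raw measurement it needs is absent.
    """
    if thresholds is None:
        thresholds = AuditThresholds()
    large = (
        None
        if metadata.raw_pennation_deg is None
        else metadata.raw_pennation_deg > thresholds.large_pennation_deg
    )
    far = (
        None
        if metadata.raw_sarcomere_um is None
        else abs(1.0 - thresholds.l_s_opt_um / metadata.raw_sarcomere_um)
        > thresholds.sarcomere_deviation
    )
    return GradeInputs(large_pennation=large, sarcomere_far_from_optimal=far, thresholds=thresholds)


@dataclass(frozen=True)
class Finding:
    simplification: str
    parameter: str
    uncertainty: Uncertainty
    impact: Impact
    rationale: str
    evidence: str


@dataclass(frozen=True)
class AuditReport:
    name: str
    findings: List[Finding]
    thresholds: AuditThresholds
    scope_note: str = (
        "Findings reflect potential uncertainty in contraction dynamics only; "
        "they do not measure overall simulation accuracy."
    )

    @property
    def summary_counts(self) -> dict:
        out: dict = {"n_findings": len(self.findings)}
        for f in self.findings:
            out[f.impact] = out.get(f.impact, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scope_note": self.scope_note,
            "thresholds": self.thresholds.model_dump(),
            "summary": self.summary_counts,
            "findings": [f.__dict__ for f in self.findings],
        }

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        kw.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kw)

    def to_text(self) -> str:
        lines = [f"Provenance audit: {self.name}", self.scope_note, ""]
        if not self.findings:
            lines.append("No simplification rules fired.")
        for f in self.findings:
            lines.append(
                f"- {f.simplification} [{f.parameter}] "
                f"uncertainty={f.uncertainty} impact={f.impact}"
            )
            lines.append(f"    {f.rationale}")
            lines.append(f"    evidence: {f.evidence}")
        return "\n".join(lines)


def _q(flag: Optional[bool]) -> bool:
    """Unknown qualifier counts as holding (audit errs on the cautious side)."""
    return True if flag is None else flag


def audit(
    metadata: ProvenanceMetadata, thresholds: AuditThresholds | None = None
) -> AuditReport:
    """Evaluate the nine simplification rules over one metadata record.

    Deterministic: rules are checked in the fixed taxonomy order, so
    identical metadata yields a byte-identical report.
    """
    gi = grade_thresholds(metadata, thresholds)
    m = metadata
    findings: List[Finding] = []

    def add(simpl, parameter, uncertainty, impact, rationale, evidence):
        findings.append(Finding(simpl, parameter, uncertainty, impact, rationale, evidence))

    # 1. optimal at rest -- fiber length
    if not m.fiber_scaled_to_optimal:
        unc = "large" if _q(gi.sarcomere_far_from_optimal) else "small"
        imp = "severe" if unc == "large" else "neglectable"
        add(
            "optimal_at_rest_fiber_length",
            "l_opt_f",
            unc,
            imp,
            "Fiber length measured at the anatomical fixation position is "
            "used as the optimal fiber length; severe unless the muscle "
            "operates around optimal length within its ROM.",
            f"fiber_scaled_to_optimal=False, raw_sarcomere_um={m.raw_sarcomere_um}",
        )

    # 2. uniform optimal sarcomere length
    if m.fiber_scaled_to_optimal and m.uniform_optimal_sarcomere:
        add(
            "uniform_optimal_sarcomere_length",
            "l_opt_f",
            "small",
            "neglectable",
            "One optimal sarcomere length is assumed for all muscles; small "
            "unless the true optimum differs much from the chosen value, "
            "and neglectable unless the muscle reaches extreme lengths "
            "within its ROM.",
            f"uniform_optimal_sarcomere=True, l_s_opt={gi.thresholds.l_s_opt_um} um",
        )

    # 3. fixed pennation angle (in projected PCSA)
    if m.pennation_raw_used_in_projected_pcsa:
        escal = _q(gi.large_pennation) and _q(gi.sarcomere_far_from_optimal)
        unc = "considerable" if escal else "small"
        imp = "considerable" if escal else "neglectable"
        add(
            "fixed_pennation_angle",
            "f_iso_max",
            unc,
            imp,
            "The raw pennation angle is kept while the fiber is rescaled to "
            "optimal length in projected PCSA; considerable only when the "
            "raw pennation is large and the raw sarcomere is far from "
            "optimal.",
            f"pennation_raw_used_in_projected_pcsa=True, "
            f"raw_pennation_deg={m.raw_pennation_deg}, "
            f"raw_sarcomere_um={m.raw_sarcomere_um}",
        )

    # 4. inherited fiber length (cohort mix in PCSA)
    if m.fiber_length_source_cohort != m.volume_source_cohort:
        add(
            "inherited_fiber_length",
            "f_iso_max",
            "considerable",
            "considerable",
            "Muscle volume from one cohort is divided by fiber length from "
            "another; demographic differences (e.g. age-related fiber "
            "shortening) can bias PCSA for the entire ROM.",
            f"fiber cohort={m.fiber_length_source_cohort!r} vs "
            f"volume cohort={m.volume_source_cohort!r}",
        )

    # 5. inherited specific tension
    if m.specific_tension_source == "inherited":
        add(
            "inherited_specific_tension",
            "f_iso_max",
            "considerable",
            "considerable",
            "Specific tension estimated on one group of subjects or muscles "
            "is applied to another despite demographic or biomechanical "
            "differences.",
            "specific_tension_source='inherited'",
        )

    # 6. uniform specific tension
    if m.specific_tension_source == "uniform":
        add(
            "uniform_specific_tension",
            "f_iso_max",
            "considerable",
            "considerable",
            "A single specific tension is applied to all muscles despite "
            "fiber-type and functional-group differences.",
            "specific_tension_source='uniform'",
        )

    # 7. optimal at rest -- pennation angle
    if not m.pennation_scaled:
        escal = _q(gi.large_pennation) and _q(gi.sarcomere_far_from_optimal)
        unc = "considerable" if escal else "small"
        imp = "considerable" if escal else "neglectable"
        add(
            "optimal_at_rest_pennation",
            "alpha_opt",
            unc,
            imp,
            "Pennation angle measured at the fixation position is used as "
            "the optimal pennation angle; considerable if the raw angle is "
            "large and the raw sarcomere far from optimal, with impact at "
            "lengths below optimal within the ROM.",
            f"pennation_scaled=False, raw_pennation_deg={m.raw_pennation_deg}, "
            f"raw_sarcomere_um={m.raw_sarcomere_um}",
        )

    # 8. optimal at rest -- tendon slack length
    if m.tendon_mode == "computed_at_measurement_position":
        add(
            "optimal_at_rest_tendon",
            "l_sla_t",
            "large",
            "severe",
            "Tendon slack length is set so that fiber optimality occurs at "
            "the anatomical fixation position; severe for the entire ROM "
            "even if the uncertainty itself is small, because the parameter "
            "phase-shifts the whole expressed force-length curve.",
            "tendon_mode='computed_at_measurement_position'",
        )

    # 9. slack at rest
    if m.tendon_mode == "measured_length":
        add(
            "slack_at_rest",
            "l_sla_t",
            "large",
            "severe",
            "Tendon length measured at the fixation position is used "
            "directly as the model's tendon slack length; severe for the "
            "entire ROM even if small uncertainty exists.",
            "tendon_mode='measured_length'",
        )

    return AuditReport(name=m.name, findings=findings, thresholds=gi.thresholds)


def load_metadata_yaml(path) -> ProvenanceMetadata:
    """Load one provenance metadata record from a YAML file (schema v1)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    doc.pop("schema_version", None)
    return ProvenanceMetadata(**doc)
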