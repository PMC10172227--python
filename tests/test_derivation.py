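"""Raw-measurement -> parameter derivation: worked values, conservation laws,
and the dataset pipeline with its derivation log."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mts import (
    ArchitectureRecord,
    DerivationConfig,
    DerivationError,
    derive_dataset,
    max_isometric_force,
    normalized_fiber_length,
    pcsa_conventional,
    pcsa_projected,
    rescale_specific_tension,
    scale_fiber_length,
    scale_pennation,
    tendon_slack_length,
)
from mts.core import MusculotendonParams


class TestScaleFiberLength:
    def test_delp_rescaling_ratio(self):
        # 40 mm fiber at 2.2 um sarcomere, rescaled to 2.8 um optimum
        assert scale_fiber_length(40.0, 2.2, 2.8) == pytest.approx(50.91, abs=1e-2)

    def test_identity_at_optimal_sarcomere(self):
        assert scale_fiber_length(87.3, 2.7, 2.7) == 87.3

    def test_soleus_elongation(self):
        # soleus measured at 2.12 um: +27.4% to reach 2.70 um
        got = scale_fiber_length(100.0, 2.12, 2.70)
        assert got == pytest.approx(127.36, abs=1e-2)

    def test_rejects_nonpositive(self):
        with pytest.raises(DerivationError):
            scale_fiber_length(-1.0, 2.2, 2.7)


class TestScalePennation:
    def test_soleus_correction(self):
        assert scale_pennation(28.3, 2.12, 2.7) == pytest.approx(21.9, abs=0.05)

    def test_zero_angle_fixed_point(self):
        assert scale_pennation(0.0, 2.0, 2.7) == 0.0

    def test_identity_at_optimal_sarcomere(self):
        assert scale_pennation(17.5, 2.7, 2.7) == pytest.approx(17.5, rel=1e-12)

    def test_constant_thickness_violation(self):
        with pytest.raises(DerivationError, match="constant-thickness"):
            scale_pennation(80.0, 4.0, 2.2)

    @given(st.floats(2.3, 3.2))
    def test_monotone_decreasing_in_optimal_sarcomere(self, l_s_opt):
        lo = scale_pennation(25.0, 2.2, l_s_opt)
        hi = scale_pennation(25.0, 2.2, l_s_opt + 0.05)
        assert hi < lo


class TestPCSA:
    def test_conventional_arithmetic(self):
        assert pcsa_conventional(100.0, 10.0) == pytest.approx(10.0)
        assert pcsa_conventional(500.0, 14.6) == pytest.approx(34.25, abs=5e-3)

    def test_linearity_in_volume(self):
        assert pcsa_conventional(200.0, 10.0) == 2 * pcsa_conventional(100.0, 10.0)

    def test_projected_cosine(self):
        assert pcsa_projected(100.0, 10.0, 0.0) == pcsa_conventional(100.0, 10.0)
        assert pcsa_projected(100.0, 10.0, 60.0) == pytest.approx(5.0)
        assert pcsa_projected(100.0, 10.0, 21.9) == pytest.approx(9.28, abs=5e-3)

    def test_small_pennation_regime_bound(self):
        """Below 20 deg, projected/conventional stays within [cos20, 1]."""
        for alpha in (0.0, 5.0, 10.0, 15.0, 20.0):
            ratio = pcsa_projected(300.0, 8.0, alpha) / pcsa_conventional(300.0, 8.0)
            assert math.cos(math.radians(20.0)) - 1e-12 <= ratio <= 1.0

    @given(st.floats(10.0, 900.0), st.floats(2.0, 20.0), st.floats(1.5, 4.5))
    def test_volume_conservation_through_scaling(self, volume, l_f_raw, l_s_raw):
        """scale_fiber_length then pcsa_conventional conserves V = A*l."""
        l_opt = scale_fiber_length(l_f_raw, l_s_raw, 2.7)
        area = pcsa_conventional(volume, l_opt)
        assert area * l_opt == pytest.approx(volume, rel=1e-12)


class TestSpecificTension:
    def test_force_arithmetic(self):
        assert max_isometric_force(61.0, 10.0) == pytest.approx(610.0)
        assert max_isometric_force(37.0, 20.0) == pytest.approx(740.0)

    def test_rejects_zero_tension(self):
        with pytest.raises(DerivationError):
            max_isometric_force(0.0, 10.0)

    def test_delp_corrected_value(self):
        # 61 N/cm^2 consistent with unscaled fibers becomes 78 with the
        # 2.8/2.2 rescaled optimal fiber lengths
        assert round(rescale_specific_tension(61.0, 2.8 / 2.2)) == 78

    def test_identity_and_linear(self):
        assert rescale_specific_tension(25.0, 1.0) == 25.0
        assert rescale_specific_tension(25.0, 1.2) == pytest.approx(30.0)


class TestTendonSlackLength:
    def test_subtraction(self):
        assert tendon_slack_length(0.40, 0.05, 0.0) == pytest.approx(0.35)
        assert tendon_slack_length(0.40, 0.05, math.radians(21.9)) == pytest.approx(
            0.3536, abs=1e-4
        )

    def test_roundtrip_optimal_fiber_length(self):
        p = MusculotendonParams(
            f_iso_max=500.0, l_opt_f=0.06, alpha_opt=math.radians(15), l_opt_mt=0.31
        )
        assert normalized_fiber_length(p, p.l_opt_mt) == pytest.approx(1.0, rel=1e-12)

    def test_error_when_fiber_exceeds_mtu(self):
        with pytest.raises(ValueError, match="shorter than projected"):
            tendon_slack_length(0.04, 0.05, 0.0)


def _full_record(**over):
    base = dict(
        muscle="m",
        fiber_length_mm=44.0,
        sarcomere_length_um=2.4,
        pennation_deg=18.0,
        volume_cm3=250.0,
        mtu_length_opt_mm=300.0,
        specific_tension_ncm2=45.0,
    )
    base.update(over)
    return ArchitectureRecord(**base)


class TestDeriveDataset:
    def test_scaling_steps_logged(self):
        table, logs = derive_dataset([_full_record()])
        joined = " | ".join(logs["m"])
        assert "fiber scaled" in joined
        assert "pennation scaled" in joined
        assert len(table) == 1

    def test_missing_sarcomere_flags_optimal_at_rest(self):
        table, logs = derive_dataset([_full_record(sarcomere_length_um=None)])
        joined = " | ".join(logs["m"])
        assert "optimal-at-rest" in joined
        # raw values pass through unscaled
        assert table.loc[0, "l_opt_f_m"] == pytest.approx(0.044)

    def test_derived_values_compose_elementary_steps(self):
        table, _ = derive_dataset([_full_record()])
        l_opt_mm = scale_fiber_length(44.0, 2.4, 2.7)
        alpha = scale_pennation(18.0, 2.4, 2.7)
        pcsa = pcsa_conventional(250.0, l_opt_mm / 10.0)
        assert table.loc[0, "l_opt_f_m"] == pytest.approx(l_opt_mm / 1000.0, rel=1e-12)
        assert table.loc[0, "alpha_opt_rad"] == pytest.approx(
            math.radians(alpha), rel=1e-12
        )
        assert table.loc[0, "f_iso_max_n"] == pytest.approx(45.0 * pcsa, rel=1e-12)
        assert table.loc[0, "l_sla_t_m"] == pytest.approx(
            0.300 - (l_opt_mm / 1000.0) * math.cos(math.radians(alpha)), rel=1e-12
        )

    def test_validation_errors_collected_not_dropped(self):
        records = [
            _full_record(),
            _full_record(muscle="no_force", specific_tension_ncm2=None),
            _full_record(muscle="no_area", volume_cm3=None),
        ]
        table, logs = derive_dataset(records)
        assert len(table) == 1
        assert len(logs["__errors__"]) == 2
        assert any("no_force" in e for e in logs["__errors__"])

    def test_reported_pcsa_superseded_by_volume(self):
        table, logs = derive_dataset(
            [_full_record(pcsa_cm2=99.0, pcsa_kind="conventional")]
        )
        assert any("superseded" in line for line in logs["m"])
        assert table.loc[0, "f_iso_max_n"] != pytest.approx(45.0 * 99.0)

    def test_projected_mode_uses_scaled_angle_unless_legacy(self):
        cfg = DerivationConfig(pcsa_mode="projected")
        legacy = DerivationConfig(pcsa_mode="projected", legacy_fixed_pennation_pcsa=True)
        t_new, _ = derive_dataset([_full_record()], cfg)
        t_old, logs = derive_dataset([_full_record()], legacy)
        # scaled angle is smaller -> larger cosine -> larger projected PCSA
        assert t_new.loc[0, "f_iso_max_n"] > t_old.loc[0, "f_iso_max_n"]
        assert any("fixed-pennation-angle" in line for line in logs["m"])

    def test_measured_tendon_mode(self):
        cfg = DerivationConfig(tendon_mode="measured")
        table, logs = derive_dataset([_full_record(tendon_slack_mm=260.0)], cfg)
        assert table.loc[0, "l_sla_t_m"] == pytest.approx(0.260, rel=1e-12)
        assert any("slack-at-rest" in line for line in logs["m"])
        _, logs2 = derive_dataset([_full_record()], cfg)
        assert logs2["__errors__"]


def test_record_sanity_bounds():
    with pytest.raises(ValueError):
        _full_record(sarcomere_length_um=0.4)
    with pytest.raises(ValueError):
        _full_record(pennation_deg=95.0)
    with pytest.raises(ValueError):
        _full_record(pcsa_cm2=10.0)  # kind missing
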