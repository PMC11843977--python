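"""Physiology loading, unit handling, derived rules and allometry."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtpbpk.io import read_table, write_table
from mrtpbpk.physiology import (HEMATOCRIT, MRT_ORGANS, PLATFORM_ORGANS,
                                PhysiologyError, UnitContext, allometric_scale,
                                load_species_physiology,
                                scale_platform_physiology, validate_physiology)


class TestLoading:
    @pytest.mark.parametrize("organ,field,expected", [
        ("testis", "epithelial_volume", 1.74e-4),
        ("epididymis", "luminal_volume", 2.14e-5),
        ("testis", "rete_testis_volume", 1.56e-6),
        ("vas_deferens", "muscular_volume", 2.45e-7),
        ("prostate_gland", "interstitial_volume", 5.47e-6),
    ])
    def test_mouse_table_values(self, mouse_physiology, organ, field, expected):
        assert getattr(mouse_physiology.organ(organ), field) == pytest.approx(
            expected, rel=1e-12)

    def test_flows_converted_to_per_hour(self, mouse_physiology):
        # tabulated 0.00099 L/min plasma flow -> 0.0594 L/h
        assert mouse_physiology.organ("testis").plasma_flow == pytest.approx(
            0.00099 * 60.0, rel=1e-12)

    def test_all_required_organs_present(self, mouse_physiology):
        for organ in PLATFORM_ORGANS + MRT_ORGANS:
            assert organ in mouse_physiology.organs

    def test_lymph_flow_rule(self, mouse_physiology):
        for organ in mouse_physiology.organs.values():
            if organ.plasma_flow > 0:
                assert organ.lymph_flow * 200.0 == pytest.approx(
                    organ.plasma_flow, rel=1e-12)

    def test_lung_flow_closes_circulation(self, mouse_physiology):
        lung = mouse_physiology.organ("lung")
        total = sum(o.plasma_flow for o in mouse_physiology.organs.values()
                    if o.organ_id != "lung")
        assert lung.plasma_flow - lung.lymph_flow == pytest.approx(total,
                                                                   rel=1e-12)

    def test_missing_organ_is_structural_error(self, tmp_path):
        import importlib.resources
        df = read_table(importlib.resources.files("mrtpbpk.data") / "mouse_mrt.csv")
        df = df[df["organ"] != "testis"]
        p = tmp_path / "broken.csv"
        write_table(df, p)
        with pytest.raises(PhysiologyError, match="testis"):
            load_species_physiology("mouse", source=p)

    def test_negative_value_rejected(self, tmp_path):
        import importlib.resources
        df = read_table(importlib.resources.files("mrtpbpk.data") / "mouse_mrt.csv")
        df.loc[df.index[0], "value"] = -1.0
        p = tmp_path / "neg.csv"
        write_table(df, p)
        with pytest.raises(PhysiologyError, match="negative"):
            load_species_physiology("mouse", source=p)

    def test_unknown_species_rejected(self):
        with pytest.raises(PhysiologyError, match="unknown species"):
            load_species_physiology("ferret")

    @pytest.mark.parametrize("species,bw", [("rat", 0.25), ("monkey", 6.2),
                                            ("human", 71.0)])
    def test_other_species_load_with_tabulated_mrt(self, species, bw):
        sp = load_species_physiology(species)
        assert sp.body_weight == bw
        # cross-species table value survives platform scaling untouched
        if species == "rat":
            assert sp.organ("testis").epithelial_volume == pytest.approx(1.18e-3)


class TestUnits:
    @given(st.floats(1e-9, 1e3), st.sampled_from(["L/min", "L/h", "mL/min",
                                                  "L", "mL", "min", "h"]))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_identity(self, value, unit):
        units = UnitContext()
        back = units.from_canonical(units.to_canonical(value, unit), unit)
        assert back == pytest.approx(value, rel=1e-12)

    def test_unknown_unit(self):
        with pytest.raises(PhysiologyError):
            UnitContext().to_canonical(1.0, "furlong/fortnight")


class TestAllometry:
    def test_identity_at_equal_body_weight(self):
        assert allometric_scale(0.37, 0.25, 0.25, 0.75) == 0.37

    def test_linear_volume_scaling(self):
        assert allometric_scale(0.5, 1.0, 2.0, 1.0) == pytest.approx(1.0)

    def test_flow_power_law(self):
        # 0.003078 L/min scaled mouse(0.028 kg) -> rat(0.25 kg) at ^0.75
        got = allometric_scale(0.003078, 0.028, 0.25, 0.75)
        assert got == pytest.approx(0.0158984, rel=1e-4)

    @given(st.floats(1e-3, 1e3), st.floats(0.01, 100), st.floats(0.01, 100),
           st.floats(0.01, 100), st.sampled_from([0.75, 1.0]))
    @settings(derandomize=True, max_examples=50)
    def test_multiplicative_composition(self, v, bw_a, bw_b, bw_c, e):
        via = allometric_scale(allometric_scale(v, bw_a, bw_b, e), bw_b, bw_c, e)
        direct = allometric_scale(v, bw_a, bw_c, e)
        assert via == pytest.approx(direct, rel=1e-12)

    def test_nonpositive_body_weight_rejected(self):
        with pytest.raises(ValueError):
            allometric_scale(1.0, 0.0, 1.0, 0.75)

    def test_platform_scaling_scales_pools(self, mouse_physiology):
        scaled = scale_platform_physiology(
            dataclasses.replace(mouse_physiology, body_weight=0.28),
            bw_ref=0.028)
        assert scaled.plasma_volume == pytest.approx(
            10 * mouse_physiology.plasma_volume)
        assert scaled.organ("heart").plasma_flow == pytest.approx(
            mouse_physiology.organ("heart").plasma_flow * 10 ** 0.75)


class TestValidation:
    def test_packaged_mouse_warnings_only(self, mouse_physiology):
        findings = validate_physiology(mouse_physiology)
        assert all(f.level == "warning" for f in findings)
        # the documented blood-flow column interpretation is surfaced
        assert any("Blood Flow" in f.message for f in findings)

    def test_lymph_rule_violation_flagged(self, mouse_physiology):
        sp = dataclasses.replace(mouse_physiology,
                                 organs=dict(mouse_physiology.organs))
        bad = dataclasses.replace(sp.organ("heart"),
                                  lymph_flow=2 * sp.organ("heart").plasma_flow)
        sp.organs["heart"] = bad
        findings = validate_physiology(sp)
        assert any(f.level == "error" and f.fieldname == "lymph_flow"
                   for f in findings)

    def test_negative_volume_flagged(self, mouse_physiology):
        sp = dataclasses.replace(mouse_physiology,
                                 organs=dict(mouse_physiology.organs))
        sp.organs["testis"] = dataclasses.replace(sp.organ("testis"),
                                                  luminal_volume=-1e-6)
        findings = validate_physiology(sp)
        assert any(f.level == "error" and f.organ == "testis" for f in findings)

    def test_printed_human_testis_anomaly_flagged(self):
        sp = load_species_physiology("human")
        findings = validate_physiology(sp)
        assert any(f.organ == "testis" and f.fieldname == "epithelial_volume"
                   for f in findings)

    def test_implied_hematocrit(self, mouse_physiology):
        o = mouse_physiology.organ("seminal_vesicle")
        hct = o.blood_cell_flow / (o.blood_cell_flow + o.plasma_flow)
        assert hct == pytest.approx(HEMATOCRIT, abs=5e-4)
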