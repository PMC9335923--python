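"""Parameter loading, derivation chains and size-dependent kinetics."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopbpk.params import (
    KecRelation,
    NanoparticleSpec,
    PhysiologyTable,
    ValidationError,
    default_murine_table,
    derive_endothelial_volume,
    load_physiology,
    size_dependent_kinetics,
    stokes_einstein_diffusivity,
)

KB = 1.380649e-23


def _base_config():
    import pathlib

    src = pathlib.Path(__file__).parent.parent / "src" / "nanopbpk" / "data" / "murine.yaml"
    return yaml.safe_load(src.read_text())


class TestLoading:
    def test_fixture_roundtrip(self, murine):
        assert set(murine.organ_names) == {
            "lung", "heart", "kidney", "liver", "spleen", "gut", "other"
        }
        assert murine.systemic.dose > 0
        frame = murine.to_frame()
        assert frame.shape[0] == 7
        assert (frame["K_on_per_s"] > 0).all()

    def test_csv_export(self, murine, tmp_path):
        out = tmp_path / "params.csv"
        murine.to_csv(out)
        import pandas as pd

        back = pd.read_csv(out, index_col="organ")
        assert np.allclose(back["V_bl_L"], murine.to_frame()["V_bl_L"])

    def test_negative_volume_rejected(self):
        cfg = _base_config()
        cfg["organs"]["liver"]["V_bl"] = -1.0
        with pytest.raises(ValidationError, match="liver.V_bl"):
            PhysiologyTable.from_config(cfg)

    def test_missing_organ_field_rejected(self):
        cfg = _base_config()
        del cfg["organs"]["gut"]["Q"]
        with pytest.raises(ValidationError, match="gut"):
            PhysiologyTable.from_config(cfg)

    def test_missing_units_rejected(self):
        cfg = _base_config()
        del cfg["units"]
        with pytest.raises(ValidationError, match="units"):
            PhysiologyTable.from_config(cfg)

    def test_json_config_supported(self, tmp_path):
        import json

        p = tmp_path / "cfg.json"
        p.write_text(json.dumps(_base_config()))
        table = load_physiology(p)
        assert set(table.organ_names) == set(default_murine_table().organ_names)

    def test_vein_volume_from_total_closure(self, murine):
        # V_total = 2146 uL and equal venous/arterial split
        sum_v_bl = sum(o.V_bl for o in murine.organs.values())
        expected = (2.146e-3 - sum_v_bl) / 2.0
        assert murine.systemic.V_vein == pytest.approx(expected, rel=1e-12)
        assert murine.systemic.V_art == murine.systemic.V_vein
        closure = murine.systemic.V_art + murine.systemic.V_vein + sum_v_bl
        assert closure == pytest.approx(murine.systemic.V_total, rel=1e-12)

    def test_subset_recloses_total(self, murine):
        sub = murine.subset(("lung", "heart", "kidney", "liver", "spleen"))
        s = sub.systemic
        assert s.V_total == pytest.approx(
            s.V_vein + s.V_art + sum(o.V_bl for o in sub.organs.values())
        )


class TestEndothelialVolume:
    def test_fixture_chain(self, murine):
        # V_EC = phi_EC * V_T * l_NC_b / D_EC with phi=0.3, D_EC=5e-6
        v_t = murine.organs["lung"].V_T
        expected = 0.3 * v_t * 5.0e-8 / 5.0e-6
        assert murine.organs["lung"].V_EC == pytest.approx(expected, rel=1e-12)

    def test_zero_fraction_gives_zero_volume(self):
        assert derive_endothelial_volume(0.0, 5e-6, 1e-4, 5e-8) == 0.0

    @given(
        phi=st.floats(1e-3, 1.0),
        d_ec=st.floats(1e-7, 1e-4),
        v_t=st.floats(1e-7, 1e-2),
        l_b=st.floats(1e-9, 1e-6),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_single_expression(self, phi, d_ec, v_t, l_b):
        # independent re-evaluation of the two-step chain as one expression
        assert derive_endothelial_volume(phi, d_ec, v_t, l_b) == pytest.approx(
            (phi * v_t / d_ec) * l_b, rel=1e-12
        )

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValidationError):
            derive_endothelial_volume(0.3, -5e-6, 1e-4, 5e-8)


class TestSizeKinetics:
    REL = KecRelation(slope=5.0e-3, anchor_diameter=800.0, anchor_logKec=9.0)

    def test_diffusivity_brute_force(self):
        # constant-by-constant re-evaluation at 100 nm, 310 K, plasma viscosity
        np_spec = NanoparticleSpec(diameter=100.0, T=310.0, eta=1.2e-3,
                                   l_glyco=5.0e-7)
        r = 50e-9
        expected_D = KB * 310.0 / (6.0 * math.pi * 1.2e-3 * r)
        assert stokes_einstein_diffusivity(np_spec) == pytest.approx(
            expected_D, rel=1e-12
        )
        k_on, k_off, log_kec = size_dependent_kinetics(np_spec, self.REL)
        assert k_on == pytest.approx(expected_D / (5.0e-7) ** 2, rel=1e-12)
        assert log_kec == pytest.approx(9.0 + 5.0e-3 * (100.0 - 800.0))
        assert k_off == pytest.approx(k_on / log_kec, rel=1e-12)

    def test_doubling_diameter_halves_k_on(self):
        a = NanoparticleSpec(diameter=50.0)
        b = NanoparticleSpec(diameter=100.0)
        k_a, _, _ = size_dependent_kinetics(a, self.REL)
        k_b, _, _ = size_dependent_kinetics(b, self.REL)
        assert k_a == pytest.approx(2.0 * k_b, rel=1e-12)

    def test_anchor_identity(self):
        np_spec = NanoparticleSpec(diameter=800.0)
        _, _, log_kec = size_dependent_kinetics(np_spec, self.REL)
        assert log_kec == 9.0

    def test_out_of_validity_extrapolation_raises(self):
        # slope drives log(K_EC) <= 0 for tiny particles
        steep = KecRelation(slope=2.0e-2, anchor_diameter=800.0, anchor_logKec=9.0)
        with pytest.raises(ValidationError, match="validity"):
            size_dependent_kinetics(NanoparticleSpec(diameter=10.0), steep)

    @given(d=st.floats(4.0, 700.0))
    @settings(max_examples=50, deadline=None)
    def test_k_on_strictly_decreasing_in_diameter(self, d):
        k1, _, _ = size_dependent_kinetics(NanoparticleSpec(diameter=d), self.REL)
        k2, _, _ = size_dependent_kinetics(NanoparticleSpec(diameter=d * 1.1),
                                           self.REL)
        assert k2 < k1

    def test_off_on_ratio_is_inverse_log_kec(self, murine):
        for organ in murine.organ_names:
            o = murine.organs[organ]
            log_kec = murine.kec.log_kec(murine.np_spec.diameter, organ)
            assert o.K_off / o.K_on == pytest.approx(1.0 / log_kec, rel=1e-12)

    def test_with_nanoparticle_rederives_rates(self, murine):
        small = murine.with_nanoparticle(15.0)
        assert small.np_spec.diameter == 15.0
        for organ in murine.organ_names:
            assert small.organs[organ].K_on > murine.organs[organ].K_on
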