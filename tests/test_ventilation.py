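"""Wall-motion kinematics: exact cubic radius updates, flow partitioning,
compliance rules and cycle closure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from acinosim.fixtures import fixture_tree
from acinosim.ventilation import (BreathingWaveform, ComplianceRule,
                                  ConservationError, build_schedule,
                                  generation_flow, max_expansion_factor,
                                  radius_increment, unit_volume_rate)


class TestRadiusIncrement:
    def test_zero_volume_change(self):
        assert radius_increment(0.105, 0.0, 0.75) == 0.0

    def test_volume_doubling_scales_radius_by_cbrt2(self):
        r = 0.105
        dv = 0.75 * 4.0 / 3.0 * math.pi * r ** 3
        assert radius_increment(r, dv, 0.75) == pytest.approx(
            r * (2.0 ** (1.0 / 3.0) - 1.0), rel=1e-12)

    def test_half_radius_contraction(self):
        r = 0.2
        dv = -0.75 * 4.0 / 3.0 * math.pi * r ** 3 * (1.0 - 0.5 ** 3)
        assert radius_increment(r, dv, 0.75) == pytest.approx(-0.5 * r, rel=1e-12)

    def test_contraction_beyond_volume_is_domain_error(self):
        r = 0.1
        with pytest.raises(ValueError):
            radius_increment(r, -2.0 * 0.75 * 4 / 3 * math.pi * r ** 3, 0.75)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(r=st.floats(0.05, 0.2),
           f=st.sampled_from([0.75, 0.97]),
           frac=st.floats(-0.8, 0.8))
    def test_closed_form_matches_root_finder(self, r, f, frac):
        """The closed form is the root of the finite-increment cubic
        dV = f*(4/3)*pi*((r+dr)^3 - r^3) to 1e-12 relative."""
        dv = frac * f * 4.0 / 3.0 * math.pi * r ** 3
        dr = radius_increment(r, dv, f)

        def resid(x):
            return f * 4.0 / 3.0 * math.pi * ((r + x) ** 3 - r ** 3) - dv

        oracle = brentq(resid, -r * 0.999, 2.0 * r, xtol=1e-16, rtol=1e-15)
        assert dr == pytest.approx(oracle, rel=1e-12, abs=1e-15)


class TestFlowPartition:
    def test_max_expansion_factor_values(self):
        assert round(max_expansion_factor(3000, 6000), 2) == 0.26
        assert max_expansion_factor(1234, 1234) == 0.0
        assert max_expansion_factor(1, 8) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            max_expansion_factor(6000, 3000)

    def test_generation_flow_halving(self):
        assert generation_flow(15.0, 0) == 15.0
        assert generation_flow(15.0, 16) == pytest.approx(15.0 / 65536.0)
        assert generation_flow(15.0, 16) == pytest.approx(2.289e-4, rel=1e-3)
        assert generation_flow(0.0, 5) == 0.0
        with pytest.raises(ValueError):
            generation_flow(1.0, -1)

    def test_unit_volume_rate_uses_fraction_and_multiplicity(self, full_tree):
        tbu = full_tree.units[0]
        assert tbu.alveolar_volume_fraction == pytest.approx(0.03)
        assert unit_volume_rate(15.0, tbu) == pytest.approx(0.45)
        dbu = full_tree.units[2]
        assert dbu.alveolar_volume_fraction == pytest.approx(0.72)
        assert dbu.multiplicity == 64
        assert unit_volume_rate(15.0, dbu) == pytest.approx(0.16875)


class TestWaveform:
    def test_tidal_volume_from_flow_and_duration(self):
        wf = BreathingWaveform(q_inlet_lpm=15.0, inhale_s=2.0)
        assert wf.tidal_ml == pytest.approx(500.0, rel=1e-12)
        wf4 = BreathingWaveform(q_inlet_lpm=15.0, inhale_s=4.0)
        assert wf4.tidal_ml == pytest.approx(1000.0, rel=1e-12)

    def test_inconsistent_tidal_volume_rejected(self):
        with pytest.raises(ValueError):
            BreathingWaveform(q_inlet_lpm=15.0, inhale_s=2.0, tidal_ml=400.0)

    def test_signed_flow(self):
        wf = BreathingWaveform(q_inlet_lpm=15.0, inhale_s=2.0)
        assert wf.q_oral(1.0) > 0
        assert wf.q_oral(3.0) == pytest.approx(-wf.q_oral(1.0))


class TestSchedule:
    def test_cycle_closes_on_frc_radii(self, schedule_tv500, schedule_tv1000):
        for s in (schedule_tv500, schedule_tv1000):
            assert np.max(np.abs(s.r[:, -1] - s.r[:, 0])) <= 1e-9 * s.r[:, 0].max()

    def test_mass_balance_through_stiffening_and_cap(self, schedule_tv500,
                                                     schedule_tv1000):
        """Sum of class volume rates reproduces the acinus inlet flow at
        every step, including after redistribution."""
        for s in (schedule_tv500, schedule_tv1000):
            rel = np.abs(s.rate_acinus.sum(axis=0) - s.q_acinus) / np.abs(s.q_acinus)
            assert rel.max() <= 1e-9

    def test_stiffening_engages_at_500ml(self, schedule_tv500, schedule_tv1000):
        assert not schedule_tv500.stiffened[:schedule_tv500.n_inhale].any()
        s = schedule_tv1000
        onset = s.t[np.argmax(s.stiffened)]
        assert onset == pytest.approx(2.0, abs=2 * s.dt)

    def test_cap_is_never_exceeded(self, full_tree, schedule_tv1000):
        cap = full_tree.config.max_expansion_factor
        r0 = schedule_tv1000.r[:, 0]
        assert np.all(schedule_tv1000.r <= r0[:, None] * (1 + cap) * (1 + 1e-12))
        assert schedule_tv1000.capped.any()

    def test_time_reversal_symmetry(self, schedule_tv500):
        assert np.allclose(schedule_tv500.r, schedule_tv500.r[:, ::-1],
                           rtol=0, atol=1e-18)

    def test_zero_flow_waveform_gives_static_schedule(self, full_tree):
        s = build_schedule(full_tree, BreathingWaveform(q_inlet_lpm=0.0,
                                                        inhale_s=2.0))
        assert np.all(s.drdt == 0.0)
        assert np.all(s.r == s.r[:, :1])

    def test_homogeneous_limit_without_compliance_rules(self, full_tree):
        """With stiffening disabled and no binding cap, every class expands
        smoothly and no compliance flag fires."""
        rule = ComplianceRule(stiffening_threshold_ml=1e9, cap_factor=10.0)
        s = build_schedule(full_tree, BreathingWaveform(q_inlet_lpm=15.0,
                                                        inhale_s=4.0), rule)
        assert not s.stiffened.any()
        assert not s.capped.any()
        # per-alveolus trajectories within a class are identical by
        # construction; rates stay proportional to the configured fractions
        fr = full_tree.class_fractions()
        ratio = s.rate_acinus[:, 0] / s.q_acinus[0]
        assert np.allclose(ratio, fr, rtol=1e-12)

    def test_overdriven_fixture_raises_conservation_error(self):
        tree = fixture_tree("tiny")
        with pytest.raises(ConservationError):
            build_schedule(tree, BreathingWaveform(q_inlet_lpm=15.0,
                                                   inhale_s=2.0))

    def test_schedule_frame_export(self, schedule_tv500):
        df = schedule_tv500.to_frame()
        assert {"time_s", "unit", "generation", "radius_mm", "drdt_mm_s",
                "stiffened", "capped"} <= set(df.columns)
        assert (df.radius_mm > 0).all()
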