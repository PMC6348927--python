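"""Reduced-order flow field: profile normalisation, cavity boundary
conditions, conservation audits and the recirculating-to-radial transition."""

import numpy as np
import pytest

from acinosim.flowfield import REGIME_RATIO_SENTINEL, FlowField
from acinosim.geometry import CLASS_OF_GENERATION
from acinosim.ventilation import BreathingWaveform, build_schedule


def disc_quadrature(ff, alv, t, n=400):
    """Numerical flux of the neck plug field through the alveolus mouth."""
    nvec = alv.outward_axis
    t1 = np.cross(nvec, [0.0, 0.0, 1.0])
    if np.linalg.norm(t1) < 1e-9:
        t1 = np.cross(nvec, [0.0, 1.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(nvec, t1)
    nr = alv.neck_radius
    xs = np.linspace(-nr, nr, n)
    X, Y = np.meshgrid(xs, xs)
    m = X ** 2 + Y ** 2 <= nr ** 2
    mid = alv.mouth_point + 0.3 * (alv.center - alv.mouth_point)
    pts = mid[None, :] + X[m][:, None] * t1 + Y[m][:, None] * t2
    us = np.array([ff.neck_velocity(p, alv.index, t) for p in pts])
    return float((us @ nvec).sum() * (xs[1] - xs[0]) ** 2)


class TestDuctVelocity:
    def test_parabolic_profile(self, full_tree, flow_tv500):
        d = full_tree.ducts[0]
        mid = d.proximal_point + 0.5 * d.length * d.axis
        u_c = flow_tv500.duct_velocity(mid, 0, 1.0)
        q = flow_tv500.duct_flow(0, 0.5 * d.length, 1.0)
        u_mean = q / (np.pi * d.radius ** 2)
        assert np.linalg.norm(u_c) == pytest.approx(2.0 * u_mean, rel=1e-12)
        u_w = flow_tv500.duct_velocity(mid + d.radius * d.n1, 0, 1.0)
        assert np.linalg.norm(u_w) < 1e-15

    def test_profile_integrates_to_flow_rate(self, full_tree, flow_tv500):
        d = full_tree.ducts[0]
        s = 0.5 * d.length
        n = 300
        xs = np.linspace(-d.radius, d.radius, n)
        X, Y = np.meshgrid(xs, xs)
        m = X ** 2 + Y ** 2 <= d.radius ** 2
        pts = (d.proximal_point[None, :] + s * d.axis[None, :]
               + X[m][:, None] * d.n1[None, :] + Y[m][:, None] * d.n2[None, :])
        us = np.array([flow_tv500.duct_velocity(p, 0, 1.0) for p in pts])
        q_num = (us @ d.axis).sum() * (xs[1] - xs[0]) ** 2
        assert q_num == pytest.approx(flow_tv500.duct_flow(0, s, 1.0), rel=5e-3)

    def test_point_outside_lumen_rejected(self, full_tree, flow_tv500):
        d = full_tree.ducts[0]
        with pytest.raises(ValueError):
            flow_tv500.duct_velocity(d.proximal_point + 2 * d.radius * d.n1,
                                     0, 1.0)


class TestAlveolarVelocity:
    def test_zero_drivers_give_zero_velocity(self, full_tree):
        s0 = build_schedule(full_tree, BreathingWaveform(q_inlet_lpm=0.0,
                                                         inhale_s=2.0))
        ff = FlowField(full_tree, s0)
        a = full_tree.alveoli[0]
        p = a.center + 0.5 * a.radius * np.array([0, 0, 1.0])
        assert np.linalg.norm(ff.alveolar_velocity(p, a.index, 1.0)) == 0.0

    def test_wall_normal_speed_matches_wall_motion(self, full_tree,
                                                   schedule_tv500, flow_tv500):
        """No-slip on the moving wall: the normal velocity at the cavity
        surface equals dr/dt exactly (vortex and jet are tangential there)."""
        for aidx in (0, 120, 290):
            a = full_tree.alveoli[aidx]
            cls = a.deformation_class
            i = schedule_tv500.step_index(1.0)
            r_now = schedule_tv500.r[cls, i]
            nhat = np.array([0.0, 0.0, 1.0])
            u = flow_tv500.alveolar_velocity(a.center + r_now * nhat, a.index, 1.0)
            assert u @ nhat == pytest.approx(schedule_tv500.drdt[cls, i],
                                             rel=1e-9, abs=1e-18)

    @pytest.mark.parametrize("aidx", [0, 150, 291])
    def test_mouth_flux_quadrature_matches_schedule_rate(self, full_tree,
                                                         flow_tv500, aidx):
        """Flux through the alveolus mouth equals the schedule's dV/dt to
        better than 0.5%."""
        a = full_tree.alveoli[aidx]
        i = flow_tv500.step_index(1.0)
        target = flow_tv500.rate_alv[a.deformation_class, i]
        flux = disc_quadrature(flow_tv500, a, 1.0)
        assert flux == pytest.approx(target, rel=5e-3)


class TestConservationAndRegime:
    def test_generation_mass_audit(self, flow_tv500, rng):
        times = rng.uniform(0.0, 4.0, 10)
        worst = max(flow_tv500.mass_audit(t) for t in times)
        assert worst <= 1e-6

    def test_regime_ratio_trends(self, full_tree, flow_tv500):
        """Recirculation dominates proximally, radial flow distally: the
        flow-regime ratio rises across the deformation classes and from
        generation 17 to 21."""
        rr = flow_tv500.regime_ratio_by_generation(1.0)
        assert rr[21] > rr[17]
        by_class = {}
        for g, v in rr.items():
            by_class.setdefault(CLASS_OF_GENERATION[g], []).append(v)
        means = [np.mean(by_class[c]) for c in range(4)]
        assert all(means[i + 1] > means[i] for i in range(3))

    def test_regime_ratio_zero_wall_motion(self, full_tree):
        s0 = build_schedule(full_tree, BreathingWaveform(q_inlet_lpm=0.0,
                                                         inhale_s=2.0))
        ff = FlowField(full_tree, s0)
        assert ff.flow_regime_ratio(0, 1.0) == 0.0

    def test_regime_ratio_sentinel_when_shear_vanishes(self, full_tree,
                                                       schedule_tv500):
        ff = FlowField(full_tree, schedule_tv500)
        # forcing the duct flow to zero at a sac leaves only the wall motion
        ff.q_duct_in[:] = 0.0
        sac = next(a for a in full_tree.alveoli if a.is_sac)
        assert ff.flow_regime_ratio(sac.index, 1.0) == REGIME_RATIO_SENTINEL

    def test_exhalation_reverses_the_field(self, full_tree, flow_tv500):
        d = full_tree.ducts[0]
        p_duct = d.proximal_point + 0.5 * d.length * d.axis
        a = full_tree.alveoli[10]
        p_alv = a.center + 0.4 * a.radius * np.array([0, 0, 1.0])
        # the mirror of the schedule interval [1.0, 1.001) is (2.999, 3.0]
        u_in = flow_tv500.velocity(p_duct, 1.0)
        u_ex = flow_tv500.velocity(p_duct, 2.9995)
        assert np.allclose(u_ex, -u_in, rtol=1e-12, atol=1e-20)
        # cavity radii are sampled at step starts, so the mirrored cavity
        # field agrees to one schedule step in r (~1e-4 relative)
        u_in = flow_tv500.velocity(p_alv, 1.0)
        u_ex = flow_tv500.velocity(p_alv, 2.9995)
        assert np.allclose(u_ex, -u_in, rtol=5e-4, atol=1e-18)

    def test_velocity_outside_domain_raises(self, flow_tv500):
        with pytest.raises(ValueError):
            flow_tv500.velocity(np.array([0.5, 0.5, 0.5]), 1.0)
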