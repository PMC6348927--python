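"""Lagrangian tracking of micron particles through the breathing cycle.

Each particle obeys a drag + gravity point-force balance,

    dv/dt = (u_air - v) / tau_eff + g,

with the Stokes relaxation time ``tau = rho_p d^2 / (18 mu)`` corrected by
the Schiller-Naumann finite-Reynolds drag factor,
``tau_eff = tau / (1 + 0.15 Re^0.687)``.  The velocity update integrates
this linear ODE exactly over a step (stiff-safe for tau << dt); positions
follow by a trapezoidal update.  Particles deposit on wall contact (centre
within one particle radius of a surface), hand off between the resolved
units at the outlet/inlet planes (downstream during inhalation, to a
randomly chosen parent outlet during exhalation) and exit the domain when
they cross the generation-16 inlet while exhaling.

The tracker is vectorised over all particles of all sizes at once; a run
of a full cycle produces a :class:`DepositionRecord` with per-particle
deposition sites and per-(generation, region, phase, size) fractions, the
deposition fraction being counts over particles entering the
generation-16 inlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import ParticlesConfig
from .flowfield import FlowField
from .geometry import AcinarTree, REGION_OF_GENERATION
from .ventilation import WallMotionSchedule

STATUS_PENDING, STATUS_SUSPENDED, STATUS_DEPOSITED, STATUS_EXITED = 0, 1, 2, 3
PHASE_INHALE, PHASE_EXHALE = 0, 1
REGIONS = ("proximal", "mid", "distal")


class TrackerError(RuntimeError):
    """Raised on non-finite particle state or census imbalance."""


def drag_coefficient(reynolds):
    """Schiller-Naumann drag coefficient ``Cd = 24/Re (1 + 0.15 Re^0.687)``.

    Diverges as 24/Re for Re -> 0 (Stokes limit); use
    :func:`schiller_naumann_factor` for the regularised product
    ``Cd Re / 24``.
    """
    re = np.asarray(reynolds, dtype=float)
    if np.any(re < 0):
        raise ValueError("Reynolds number must be non-negative")
    with np.errstate(divide="ignore"):
        cd = 24.0 / re * schiller_naumann_factor(re)
    return cd if cd.ndim else float(cd)


def schiller_naumann_factor(reynolds):
    """Regularised drag correction ``Cd Re / 24 = 1 + 0.15 Re^0.687``;
    exactly 1 in the Stokes limit Re = 0."""
    re = np.asarray(reynolds, dtype=float)
    out = 1.0 + 0.15 * re ** 0.687
    return out if out.ndim else float(out)


def settling_velocity(d_p: float, rho_p: float, mu_air: float,
                      g: float = 9.81) -> float:
    """Stokes terminal settling speed ``rho_p d^2 g / (18 mu)``."""
    if d_p < 0:
        raise ValueError("diameter must be non-negative")
    return rho_p * d_p ** 2 * g / (18.0 * mu_air)


def relaxation_time(d_p, rho_p: float, mu_air: float):
    """Stokes relaxation time ``rho_p d^2 / (18 mu)``."""
    return rho_p * np.asarray(d_p) ** 2 / (18.0 * mu_air)


def drag_step(pos, vel, u_air, d_p, dt, rho_p, mu_air, rho_air, g_vec):
    """One analytic integration step of the drag + gravity force balance.

    ``g_vec`` may be a single (3,) vector or per-particle (N, 3).  Returns
    updated (pos, vel); position uses the trapezoidal rule on the
    velocities.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    vel = np.atleast_2d(np.asarray(vel, dtype=float))
    u_air = np.atleast_2d(np.asarray(u_air, dtype=float))
    d = np.atleast_1d(np.asarray(d_p, dtype=float))
    g_vec = np.asarray(g_vec, dtype=float)
    if g_vec.ndim == 1:
        g_vec = np.broadcast_to(g_vec, pos.shape)
    tau0 = relaxation_time(d, rho_p, mu_air)
    slip = np.linalg.norm(u_air - vel, axis=1)
    re = rho_air * slip * d / mu_air
    tau = tau0 / schiller_naumann_factor(re)
    v_inf = u_air + tau[:, None] * g_vec
    decay = np.exp(-dt / tau)[:, None]
    v_new = v_inf + (vel - v_inf) * decay
    pos_new = pos + 0.5 * dt * (vel + v_new)
    if not (np.all(np.isfinite(pos_new)) and np.all(np.isfinite(v_new))):
        bad = np.nonzero(~np.isfinite(pos_new).all(axis=1)
                         | ~np.isfinite(v_new).all(axis=1))[0]
        raise TrackerError(f"non-finite particle state for indices {bad[:10]}")
    return pos_new, v_new


@dataclass
class ParticleState:
    """Single-particle view used by the operation-level API."""

    diameter: float
    density: float
    position: np.ndarray
    velocity: np.ndarray
    unit: int = 0
    generation: int = 16
    status: int = STATUS_SUSPENDED
    surface_id: Optional[tuple] = None
    deposit_time: Optional[float] = None
    injection_time: float = 0.0


def step_particle(p: ParticleState, u_air, dt: float,
                  mu_air: float = 1.81e-5, rho_air: float = 1.2,
                  g_vec=(0.0, 0.0, -9.81)) -> ParticleState:
    """Advance one suspended particle by ``dt`` (deposited particles are
    returned unchanged)."""
    if p.status != STATUS_SUSPENDED:
        return p
    if dt <= 0:
        raise ValueError("dt must be positive")
    pos, vel = drag_step(p.position, p.velocity, u_air, p.diameter, dt,
                         p.density, mu_air, rho_air, np.asarray(g_vec))
    p.position, p.velocity = pos[0], vel[0]
    return p


# ----------------------------------------------------------------------

@dataclass
class DepositionRecord:
    """Outcome of a breathing-cycle run: per-particle fate arrays and
    aggregated deposition fractions."""

    diameters_um: np.ndarray        # distinct sizes
    d_um: np.ndarray                # per particle
    injection_time: np.ndarray
    status: np.ndarray
    dep_generation: np.ndarray      # -1 if not deposited
    dep_phase: np.ndarray           # -1 / PHASE_INHALE / PHASE_EXHALE
    dep_time: np.ndarray
    dep_normal_z: np.ndarray        # lab-frame z of the into-air normal
    dep_kind: np.ndarray            # 0 duct, 1 alveolus, -1
    exit_time: np.ndarray
    exit_radial_fraction: np.ndarray
    injection_radial_fraction: np.ndarray
    inhale_s: float
    max_unit: np.ndarray = None     # deepest resolved unit each particle saw

    def n_injected(self, d_um: Optional[float] = None) -> int:
        m = self._size_mask(d_um)
        return int(np.sum(m & (self.status != STATUS_PENDING)))

    def _size_mask(self, d_um):
        if d_um is None:
            return np.ones_like(self.d_um, dtype=bool)
        return np.isclose(self.d_um, d_um)

    def deposition_fraction(self, d_um: Optional[float] = None,
                            region: Optional[str] = None,
                            generation: Optional[int] = None,
                            phase: Optional[int] = None) -> float:
        """Deposited count in the selected slice over particles entering the
        generation-16 inlet (of that size class)."""
        m = self._size_mask(d_um) & (self.status != STATUS_PENDING)
        n_in = int(np.sum(m))
        if n_in == 0:
            return 0.0
        dep = m & (self.status == STATUS_DEPOSITED)
        if region is not None:
            gens = [g for g, r in REGION_OF_GENERATION.items() if r == region]
            dep &= np.isin(self.dep_generation, gens)
        if generation is not None:
            dep &= self.dep_generation == generation
        if phase is not None:
            dep &= self.dep_phase == phase
        return float(np.sum(dep)) / n_in

    def suspended_fraction(self, d_um: Optional[float] = None) -> float:
        m = self._size_mask(d_um) & (self.status != STATUS_PENDING)
        if not m.any():
            return 0.0
        return float(np.sum(m & (self.status == STATUS_SUSPENDED))) / np.sum(m)

    def census_ok(self) -> bool:
        active = self.status != STATUS_PENDING
        fates = (np.sum(self.status == STATUS_SUSPENDED)
                 + np.sum(self.status == STATUS_DEPOSITED)
                 + np.sum(self.status == STATUS_EXITED))
        return int(np.sum(active)) == int(fates)

    def to_frame(self) -> pd.DataFrame:
        """Aggregated table keyed by (generation, region, phase, d_um)."""
        rows = []
        for d in self.diameters_um:
            n_in = self.n_injected(d)
            for gen, region in REGION_OF_GENERATION.items():
                for phase, pname in ((PHASE_INHALE, "inhale"),
                                     (PHASE_EXHALE, "exhale")):
                    m = (self._size_mask(d)
                         & (self.status == STATUS_DEPOSITED)
                         & (self.dep_generation == gen)
                         & (self.dep_phase == phase))
                    n_dep = int(np.sum(m))
                    rows.append(dict(
                        generation=gen, region=region, phase=pname,
                        d_um=d, n_injected=n_in, n_deposited=n_dep,
                        deposition_fraction=n_dep / n_in if n_in else 0.0))
        return pd.DataFrame(rows)


def deposition_fraction(record: DepositionRecord, **selector) -> float:
    """Module-level convenience wrapper around the record method."""
    return record.deposition_fraction(**selector)


# ----------------------------------------------------------------------

class ParticleTracker:
    """Vectorised Lagrangian engine over one resolved acinar tree."""

    def __init__(self, tree: AcinarTree, schedule: WallMotionSchedule,
                 config: Optional[ParticlesConfig] = None,
                 flowfield: Optional[FlowField] = None):
        self.tree = tree
        self.schedule = schedule
        self.config = config or ParticlesConfig()
        self.flow = flowfield or FlowField(tree, schedule,
                                           vortex_strength=self.config.vortex_strength)
        self.rng = np.random.default_rng(self.config.seed)

        # unit-level caches
        self.unit_gl = {u.index: u.gravity_local * self.config.gravity_m_s2
                        for u in tree.units}
        self.unit_ducts = {}
        for u in tree.units:
            dl = [tree.ducts[i] for i in u.duct_indices]
            self.unit_ducts[u.index] = dict(
                idx=np.array([d.index for d in dl]),
                p0=np.array([d.proximal_point for d in dl]),
                ax=np.array([d.axis for d in dl]),
                n1=np.array([d.n1 for d in dl]),
                n2=np.array([d.n2 for d in dl]),
                R=np.array([d.radius for d in dl]),
                L=np.array([d.length for d in dl]),
                gen=np.array([d.generation for d in dl]),
                capped_end=np.array([not d.children
                                     and tree.units[d.unit_index].child_unit < 0
                                     for d in dl]),
                inlet_pos=int(np.nonzero(np.array(
                    [d.index == u.inlet_duct for d in dl]))[0][0]),
                terminal=np.array([not d.children for d in dl]),
            )
        # per-duct sorted mouth stations for Q(s)
        self.duct_stations = {}
        for d in tree.ducts:
            members = np.nonzero(tree.alv_duct == d.index)[0]
            self.duct_stations[d.index] = np.sort(tree.alv_station[members])
        # per-unit alveolus arrays
        self.unit_alv = {}
        for u in tree.units:
            idx = tree.unit_alveoli(u.index)
            self.unit_alv[u.index] = dict(
                idx=idx,
                center=tree.alv_center[idx],
                cls=tree.alv_class[idx],
                gen=tree.alv_gen[idx],
                duct=tree.alv_duct[idx],
                mouth=np.array([tree.alveoli[i].mouth_point for i in idx]).reshape(-1, 3),
                outward=np.array([tree.alveoli[i].outward_axis for i in idx]).reshape(-1, 3),
                nr=np.array([tree.alveoli[i].neck_radius for i in idx]),
                is_sac=np.array([tree.alveoli[i].is_sac for i in idx]),
                k_up=self.flow.k_upstream[idx] if idx.size else np.zeros(0, dtype=int),
                duct_R=np.array([tree.ducts[tree.alveoli[i].duct_index].radius
                                 for i in idx]),
                duct_ax=np.array([tree.ducts[tree.alveoli[i].duct_index].axis
                                  for i in idx]).reshape(-1, 3),
                kdt=tree.unit_kdtree(u.index),
            )

    # ------------------------------------------------------------------
    def _duct_coords(self, unit: int, pos: np.ndarray):
        """(s, rho, rho_vec) of positions w.r.t. every duct of a unit."""
        D = self.unit_ducts[unit]
        rel = pos[:, None, :] - D["p0"][None, :, :]
        s = np.einsum("mkd,kd->mk", rel, D["ax"])
        perp = rel - s[..., None] * D["ax"][None, :, :]
        rho = np.linalg.norm(perp, axis=2)
        return s, rho, perp

    def _assign(self, unit: int, pos: np.ndarray, i_sched: int):
        """Containment: per-particle best duct / alveolus / neck distances."""
        D = self.unit_ducts[unit]
        A = self.unit_alv[unit]
        M = pos.shape[0]
        s, rho, perp = self._duct_coords(unit, pos)
        inside = (s >= 0.0) & (s <= D["L"][None, :])
        # signed containment: outside the axial range the distance goes
        # negative with the overshoot so argmax still picks the nearest duct
        overshoot = np.maximum(np.maximum(-s, s - D["L"][None, :]), 0.0)
        duct_d = np.where(inside, D["R"][None, :] - rho,
                          np.minimum(D["R"][None, :] - rho, 0.0) - overshoot)
        best_duct = np.argmax(duct_d, axis=1)
        best_duct_d = duct_d[np.arange(M), best_duct]
        best_duct_d = np.where(inside[np.arange(M), best_duct],
                               best_duct_d, np.minimum(best_duct_d, 0.0))

        r_cls = self.schedule.r[:, min(i_sched, self.schedule.n_steps - 1)]
        if A["idx"].size:
            dist, loc = A["kdt"].query(pos, k=min(2, A["idx"].size))
            dist = np.atleast_2d(dist.T).T.reshape(M, -1)
            loc = np.atleast_2d(loc.T).T.reshape(M, -1)
            alv_d = r_cls[A["cls"][loc]] - dist
            pick = np.argmax(alv_d, axis=1)
            best_alv = loc[np.arange(M), pick]
            best_alv_d = alv_d[np.arange(M), pick]
            # neck capsule of the nearest alveolus, extended one neck radius
            # into the duct so the mouth jet joins the duct flow
            center = A["center"][best_alv]
            mouth = (A["mouth"][best_alv]
                     - A["nr"][best_alv][:, None] * A["outward"][best_alv])
            seg = center - mouth
            seg2 = np.einsum("md,md->m", seg, seg)
            tpar = np.clip(np.einsum("md,md->m", pos - mouth, seg)
                           / np.where(seg2 > 0, seg2, 1.0), 0.0, 1.0)
            foot = mouth + tpar[:, None] * seg
            neck_d = A["nr"][best_alv] - np.linalg.norm(pos - foot, axis=1)
        else:
            best_alv = np.full(M, -1)
            best_alv_d = np.full(M, -np.inf)
            neck_d = np.full(M, -np.inf)
            tpar = np.zeros(M)
        return dict(s=s, rho=rho, perp=perp, best_duct=best_duct,
                    best_duct_d=best_duct_d, best_alv=best_alv,
                    best_alv_d=best_alv_d, neck_d=neck_d, neck_t=tpar)

    def _velocities(self, unit: int, pos: np.ndarray, asg: dict,
                    i_sched: int) -> np.ndarray:
        """Air velocity for every particle of one unit at one time step."""
        D = self.unit_ducts[unit]
        A = self.unit_alv[unit]
        flow = self.flow
        M = pos.shape[0]
        u_air = np.zeros((M, 3))
        i = min(i_sched, self.schedule.n_steps - 1)
        r_cls = self.schedule.r[:, i]

        in_alv = asg["best_alv_d"] > 0.0
        in_neck = ~in_alv & (asg["neck_d"] > 0.0)
        # the mouth jet superposes with the duct profile where the extended
        # neck capsule overlaps the lumen
        in_duct = ~in_alv & (asg["best_duct_d"] > 0.0)

        if np.any(in_alv):
            j = asg["best_alv"][in_alv]
            cls = A["cls"][j]
            r_now = r_cls[cls]
            rel = pos[in_alv] - A["center"][j]
            rho = np.linalg.norm(rel, axis=1)
            shape = np.maximum(1.0 - (rho / r_now) ** 2, 0.0)
            u = (flow.dil[cls, i][:, None] * rel
                 + (flow.jet[cls, i] * shape)[:, None] * A["outward"][j])
            # cavity vortex driven by the local duct shear (not for sacs)
            k_v = flow.vortex_strength
            if k_v != 0.0:
                q_mouth = (flow.q_duct_in[A["duct"][j], i]
                           - A["k_up"][j] * flow.rate_alv[cls, i])
                u_mean = q_mouth / (math.pi * A["duct_R"][j] ** 2)
                w = np.cross(A["duct_ax"][j], A["outward"][j])
                wn = np.linalg.norm(w, axis=1)
                w = w / np.where(wn > 0, wn, 1.0)[:, None]
                amp = np.where(A["is_sac"][j], 0.0,
                               k_v * u_mean * (1.0 - (rho / r_now) ** 2) / r_now)
                u = u + amp[:, None] * np.cross(w, rel)
            u_air[in_alv] = u

        if np.any(in_neck):
            j = asg["best_alv"][in_neck]
            cls = A["cls"][j]
            plug = flow.rate_alv[cls, i] / (math.pi * A["nr"][j] ** 2)
            u_air[in_neck] = plug[:, None] * A["outward"][j]

        if np.any(in_duct):
            k = asg["best_duct"][in_duct]
            didx = D["idx"][k]
            s = asg["s"][in_duct, :][np.arange(k.size), k]
            rho = asg["rho"][in_duct, :][np.arange(k.size), k]
            q = np.empty(k.size)
            for dd in np.unique(didx):
                m = didx == dd
                st = self.duct_stations[dd]
                kk = np.searchsorted(st, s[m] - 1e-12)
                cls = self.flow.class_of_duct_alv[dd]
                q[m] = self.flow.q_duct_in[dd, i] - kk * self.flow.rate_alv[cls, i]
            R = D["R"][k]
            u_mean = q / (math.pi * R ** 2)
            prof = 2.0 * u_mean * np.maximum(1.0 - (rho / R) ** 2, 0.0)
            u_air[in_duct] += prof[:, None] * D["ax"][k]
        return u_air

    # ------------------------------------------------------------------
    def run_breathing_cycle(self, progress: bool = False,
                            trace_ids=None,
                            trace_every: int = 50) -> DepositionRecord:
        """Simulate one full inhale + exhale cycle and account for every
        injected particle.

        ``trace_ids`` selects particles whose trajectory snapshots
        (time, id, position, unit, status) are collected in ``self.trace``
        every ``trace_every`` steps (the basis of the snapshot CSV export).
        """
        cfg = self.config
        wf = self.schedule.waveform
        sizes = np.asarray(cfg.diameters_um, dtype=float)
        if cfg.n_per_size is not None:
            n_per = int(cfg.n_per_size)
        else:
            n_per = int(round(cfg.injection_rate_per_s * wf.inhale_s))
        n_tot = n_per * sizes.size

        rng = self.rng
        d_um = np.repeat(sizes, n_per)
        d_m = d_um * 1e-6
        # uniform injection in time over the inhale phase (or one bolus at
        # t = 0), uniform over the inlet disc in space
        if cfg.bolus:
            t_inj = np.zeros(n_per * sizes.size)
        else:
            t_inj = np.tile((np.arange(n_per) + 0.5) * wf.inhale_s / n_per,
                            sizes.size)
        fr_inj = np.sqrt(rng.uniform(0.0, 1.0, n_tot))
        phi_inj = rng.uniform(0.0, 2.0 * math.pi, n_tot)

        pos = np.zeros((n_tot, 3))
        vel = np.zeros((n_tot, 3))
        unit = np.zeros(n_tot, dtype=np.int64)
        self._unit_array = unit
        status = np.full(n_tot, STATUS_PENDING, dtype=np.int8)
        cur_gen = np.full(n_tot, self.tree.config.inlet_generation, dtype=np.int64)

        # cavity containment tag: a particle may only enter an alveolar
        # cavity through its neck; a direct duct/outside -> cavity jump in
        # one step is a wall contact (the cavity's outer wall), not transport
        alv_tag = np.full(n_tot, -1, dtype=np.int64)
        self._alv_tag = alv_tag
        max_unit = np.zeros(n_tot, dtype=np.int64)  # deepest unit visited
        self._max_unit = max_unit

        dep_gen = np.full(n_tot, -1, dtype=np.int64)
        dep_phase = np.full(n_tot, -1, dtype=np.int8)
        dep_time = np.full(n_tot, np.nan)
        dep_nz = np.full(n_tot, np.nan)
        dep_kind = np.full(n_tot, -1, dtype=np.int8)
        exit_time = np.full(n_tot, np.nan)
        exit_fr = np.full(n_tot, np.nan)

        dt = cfg.dt_s
        n_steps = int(round(wf.period_s / dt))
        inlet = self.tree.ducts[self.tree.units[0].inlet_duct]
        inj_step = np.minimum((t_inj / dt).astype(np.int64), n_steps - 1)
        self.trace = []
        trace_ids = (np.asarray(trace_ids, dtype=np.int64)
                     if trace_ids is not None else None)

        for step in range(n_steps):
            t0 = step * dt
            t_mid = t0 + 0.5 * dt
            i_sched = self.schedule.step_index(t_mid)
            phase = PHASE_INHALE if t_mid < wf.inhale_s else PHASE_EXHALE

            # inject this step's particles at the generation-16 inlet
            new = (status == STATUS_PENDING) & (inj_step == step)
            if np.any(new):
                fr = fr_inj[new]
                ph = phi_inj[new]
                radial = (np.cos(ph)[:, None] * inlet.n1[None, :]
                          + np.sin(ph)[:, None] * inlet.n2[None, :])
                pos[new] = (inlet.proximal_point[None, :]
                            + 1e-9 * inlet.axis[None, :]
                            + (fr * inlet.radius * 0.999)[:, None] * radial)
                q_in = self.flow.q_duct_in[inlet.index, i_sched]
                u_mean = q_in / (math.pi * inlet.radius ** 2)
                prof = 2.0 * u_mean * (1.0 - fr ** 2)
                vel[new] = prof[:, None] * inlet.axis[None, :]
                unit[new] = 0
                status[new] = STATUS_SUSPENDED

            live = status == STATUS_SUSPENDED
            if not np.any(live):
                continue

            unit_snapshot = unit.copy()  # handoffs move particles mid-step
            for ui in range(len(self.tree.units)):
                sel = np.nonzero(live & (unit_snapshot == ui))[0]
                if sel.size == 0:
                    continue
                P = pos[sel]
                V = vel[sel]
                asg = self._assign(ui, P, i_sched)
                u_air = self._velocities(ui, P, asg, i_sched)
                P2, V2 = drag_step(P, V, u_air, d_m[sel], dt,
                                   cfg.density_kg_m3, cfg.air_viscosity_pa_s,
                                   cfg.air_density_kg_m3, self.unit_gl[ui])
                pos[sel], vel[sel] = P2, V2

                # containment at the new position
                asg2 = self._assign(ui, P2, i_sched)
                D = self.unit_ducts[ui]
                k_in = D["inlet_pos"]
                s_in = asg2["s"][:, k_in]
                rho_in = asg2["rho"][:, k_in]
                handled = np.zeros(sel.size, dtype=bool)

                # upstream crossing of the unit inlet plane
                back = (s_in < 0.0) & (rho_in <= D["R"][k_in])
                if np.any(back):
                    ids = sel[back]
                    if ui == 0:
                        status[ids] = STATUS_EXITED
                        exit_time[ids] = t_mid
                        exit_fr[ids] = rho_in[back] / D["R"][k_in]
                    else:
                        self._handoff_upstream(ui, ids, pos, vel, asg2, back,
                                               cur_gen)
                    handled |= back

                # downstream crossing of an outlet plane (terminal ducts)
                child = self.tree.units[ui].child_unit
                if child >= 0:
                    term = np.nonzero(D["terminal"])[0]
                    s_t = asg2["s"][:, term]
                    rho_t = asg2["rho"][:, term]
                    crossed = ((s_t > D["L"][term][None, :])
                               & (s_t - D["L"][term][None, :] < 5e-4)
                               & (rho_t <= D["R"][term][None, :]))
                    over = ~handled & crossed.any(axis=1)
                    if np.any(over):
                        kk = term[np.argmax(crossed[over], axis=1)]
                        self._handoff_downstream(ui, sel[over], pos, vel,
                                                 asg2, over, cur_gen, kk)
                        handled |= over

                # deposition on contact; a cavity reached without passing
                # through its neck was entered through the septal wall
                live_local = ~handled & (status[sel] == STATUS_SUSPENDED)
                d_dom = np.maximum(asg2["best_alv_d"],
                                   np.maximum(asg2["neck_d"],
                                              asg2["best_duct_d"]))
                A = self.unit_alv[ui]
                if A["idx"].size:
                    j_glob = A["idx"][asg2["best_alv"]]
                    in_cav = asg2["best_alv_d"] > 0.0
                    # the authorising channel is the neck capsule (within one
                    # neck radius of the mouth axis); crossing the cavity
                    # boundary anywhere else is a septal-wall contact
                    in_channel = asg2["neck_d"] > 0.0
                    tagged = alv_tag[sel] == j_glob
                    illegit = in_cav & ~in_channel & ~tagged
                    tag_now = np.where(in_channel | (in_cav & tagged),
                                       j_glob, -1)
                else:
                    illegit = np.zeros(sel.size, dtype=bool)
                    tag_now = np.full(sel.size, -1, dtype=np.int64)
                hit = live_local & ((d_dom < 0.5 * d_m[sel]) | illegit)
                if np.any(hit):
                    ids = sel[hit]
                    status[ids] = STATUS_DEPOSITED
                    dep_time[ids] = t_mid
                    dep_phase[ids] = phase
                    on_alv = asg2["best_alv_d"][hit] >= np.maximum(
                        asg2["best_duct_d"][hit], asg2["neck_d"][hit])
                    A = self.unit_alv[ui]
                    R_lab = self.tree.units[ui].rotation
                    zrow = R_lab[2, :]
                    gen = np.where(
                        on_alv & (asg2["best_alv"][hit] >= 0),
                        A["gen"][asg2["best_alv"][hit]] if A["idx"].size else 0,
                        D["gen"][asg2["best_duct"][hit]])
                    dep_gen[ids] = gen
                    dep_kind[ids] = np.where(on_alv, 1, 0)
                    # into-air normal: toward the cavity centre / duct axis
                    n_alv = (A["center"][asg2["best_alv"][hit]] - pos[ids]
                             if A["idx"].size else np.zeros((ids.size, 3)))
                    k = asg2["best_duct"][hit]
                    n_duct = -asg2["perp"][hit, :, :][np.arange(k.size), k]
                    n = np.where(on_alv[:, None], n_alv, n_duct)
                    norm = np.linalg.norm(n, axis=1)
                    n = n / np.where(norm > 0, norm, 1.0)[:, None]
                    dep_nz[ids] = n @ zrow
                # update containment + generation tags for the survivors
                ok = ~handled & (status[sel] == STATUS_SUSPENDED)
                if np.any(ok):
                    alv_tag[sel[ok]] = tag_now[ok]
                if np.any(ok):
                    in_alv = asg2["best_alv_d"] > 0
                    A = self.unit_alv[ui]
                    gen_now = np.where(
                        in_alv & (asg2["best_alv"] >= 0),
                        A["gen"][asg2["best_alv"]] if A["idx"].size else 0,
                        D["gen"][asg2["best_duct"]])
                    cur_gen[sel[ok]] = gen_now[ok]

            if trace_ids is not None and step % trace_every == 0:
                for pid in trace_ids:
                    self.trace.append((t_mid, int(pid), pos[pid].copy(),
                                       int(unit[pid]), int(status[pid])))

            if progress and step % 1000 == 0:
                n_s = int(np.sum(status == STATUS_SUSPENDED))
                print(f"t={t_mid:6.3f}s suspended={n_s}")

            # bookkeeping: every deposited particle must carry a site; a
            # breach is a hard failure, not a warning
            bad = (status == STATUS_DEPOSITED) & (dep_gen < 0)
            if np.any(bad):
                raise TrackerError(
                    f"census imbalance: {int(bad.sum())} deposited particles "
                    "have no recorded deposition site")

        self._pos, self._vel, self._status = pos, vel, status  # introspection
        return DepositionRecord(
            diameters_um=sizes, d_um=d_um, injection_time=t_inj,
            status=status.copy(), dep_generation=dep_gen,
            dep_phase=dep_phase, dep_time=dep_time, dep_normal_z=dep_nz,
            dep_kind=dep_kind, exit_time=exit_time, exit_radial_fraction=exit_fr,
            injection_radial_fraction=fr_inj, inhale_s=wf.inhale_s,
            max_unit=max_unit)

    # ------------------------------------------------------------------
    def _handoff_downstream(self, ui, ids, pos, vel, asg, mask, cur_gen, k):
        """Re-seed particles crossing an outlet plane at the child inlet,
        preserving the normalised radial coordinate, azimuth and velocity
        components."""
        tree = self.tree
        child = tree.units[ui].child_unit
        D = self.unit_ducts[ui]
        s = asg["s"][mask, :][np.arange(k.size), k]
        perp = asg["perp"][mask, :, :][np.arange(k.size), k]
        rho = np.linalg.norm(perp, axis=1)
        R_from = D["R"][k]
        fr = np.clip(rho / R_from, 0.0, 0.999)
        rho_hat = perp / np.where(rho > 0, rho, 1.0)[:, None]
        cosphi = np.einsum("md,md->m", rho_hat, D["n1"][k])
        sinphi = np.einsum("md,md->m", rho_hat, D["n2"][k])
        ax = D["ax"][k]
        v = vel[ids]
        v_ax = np.einsum("md,md->m", v, ax)
        v_r = np.einsum("md,md->m", v, rho_hat)
        that = np.cross(ax, rho_hat)
        v_t = np.einsum("md,md->m", v, that)

        cd = tree.ducts[tree.units[child].inlet_duct]
        ds = np.clip(s - D["L"][k], 0.0, None) + 1e-9
        radial = cosphi[:, None] * cd.n1[None, :] + sinphi[:, None] * cd.n2[None, :]
        pos[ids] = (cd.proximal_point[None, :] + ds[:, None] * cd.axis[None, :]
                    + (fr * cd.radius)[:, None] * radial)
        that_new = np.cross(np.broadcast_to(cd.axis, radial.shape), radial)
        vel[ids] = (v_ax[:, None] * cd.axis[None, :]
                    + v_r[:, None] * radial + v_t[:, None] * that_new)
        # particles move between unit frames; the velocity components are
        # preserved in duct-local coordinates (the units' resolved-copy
        # congruence), gravity stays lab -z via each unit's own frame
        self._unit_array[ids] = child
        self._alv_tag[ids] = -1
        self._max_unit[ids] = np.maximum(self._max_unit[ids], child)
        cur_gen[ids] = cd.generation

    def _handoff_upstream(self, ui, ids, pos, vel, asg, mask, cur_gen):
        """Place particles crossing the unit inlet during exhalation at a
        uniformly random outlet of the parent unit."""
        tree = self.tree
        parent = tree.units[ui].parent_unit
        Dp = self.unit_ducts[parent]
        term = np.nonzero(Dp["terminal"])[0]
        pick = term[self.rng.integers(0, term.size, ids.size)]

        D = self.unit_ducts[ui]
        k_in = D["inlet_pos"]
        s = asg["s"][mask, k_in]
        rho = asg["rho"][mask, k_in]
        perp = asg["perp"][mask, k_in]
        R_from = D["R"][k_in]
        fr = np.clip(rho / R_from, 0.0, 0.999)
        rho_hat = perp / np.where(rho > 0, rho, 1.0)[:, None]
        cosphi = np.einsum("md,d->m", rho_hat, D["n1"][k_in])
        sinphi = np.einsum("md,d->m", rho_hat, D["n2"][k_in])
        ax = D["ax"][k_in]
        v = vel[ids]
        v_ax = v @ ax
        v_r = np.einsum("md,md->m", v, rho_hat)
        that = np.cross(np.broadcast_to(ax, rho_hat.shape), rho_hat)
        v_t = np.einsum("md,md->m", v, that)

        p0 = Dp["p0"][pick]
        axp = Dp["ax"][pick]
        s_new = Dp["L"][pick] + np.minimum(s, -1e-9)  # s < 0: step back inside
        radial = (cosphi[:, None] * Dp["n1"][pick]
                  + sinphi[:, None] * Dp["n2"][pick])
        pos[ids] = p0 + s_new[:, None] * axp + (fr * Dp["R"][pick])[:, None] * radial
        that_new = np.cross(axp, radial)
        vel[ids] = v_ax[:, None] * axp + v_r[:, None] * radial + v_t[:, None] * that_new
        self._unit_array[ids] = parent
        self._alv_tag[ids] = -1
        cur_gen[ids] = Dp["gen"][pick]


def run_breathing_cycle(tree: AcinarTree, schedule: WallMotionSchedule,
                        config: Optional[ParticlesConfig] = None,
                        flowfield: Optional[FlowField] = None,
                        progress: bool = False) -> DepositionRecord:
    """Run one full breathing cycle and return the deposition record."""
    tracker = ParticleTracker(tree, schedule, config, flowfield)
    return tracker.run_breathing_cycle(progress=progress)
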