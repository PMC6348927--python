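"""Reduced-order, mass-consistent air velocity field over the acinar tree.

This stands in for a full moving-mesh Navier-Stokes solve.  Its contract is

* duct flow: axial Poiseuille profiles whose flow rate satisfies the
  generation-wise mass balance - the flow entering a duct equals the flow
  leaving to its children plus the alveolar mouth fluxes withdrawn along
  the way (the wall-motion schedule is the only flow source/sink);
* alveolar flow: a radial field matching the wall-normal velocity dr/dt on
  the cavity surface and carrying exactly dV/dt through the mouth disc,
  superposed with a single cavity vortex whose circulation scales with the
  local duct shear (mean velocity at the mouth).  The vortex dominates
  proximally and the radial component distally, reproducing the
  recirculating-to-radial transition along the acinus;
* exhalation is the sign-reversed inhalation field for a symmetric
  waveform (quasi-steady, low-Reynolds regime).

The radial cavity field is ``u = (alpha*rho + beta/rho^2) rho_hat`` with
``alpha`` and ``beta`` solved per class and time step from the two
boundary conditions (wall speed, mouth flux); the 1/rho^2 source is
softened inside a small core so particle tracking never sees a
singularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import AcinarTree, cap_plane_offset_fraction
from .ventilation import WallMotionSchedule

#: reported instead of the ratio when the duct shear reference flow vanishes
REGIME_RATIO_SENTINEL = 1e6


@dataclass
class FlowField:
    """Precomputed duct flows and cavity-field coefficients on the schedule
    time grid."""

    tree: AcinarTree
    schedule: WallMotionSchedule
    vortex_strength: float = 0.3
    # softened-core radius as a fraction of the cavity radius; None uses the
    # mouth-plane offset kappa_a per class, the largest core that leaves the
    # mouth-disc flux formula exact
    core_fraction: float | None = None
    blend_band_fraction: float = 0.5  # matching band, in neck radii

    def __post_init__(self) -> None:
        tree, sched = self.tree, self.schedule
        n_steps = sched.n_steps
        counts = sched.class_counts
        mult = sched.class_mult

        # per-alveolus volume rate by deformation class (m^3/s)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = (counts * mult)[:, None]
            self.rate_alv = np.where(denom > 0, sched.rate_acinus / denom, 0.0)

        # duct inlet flows: unit inlet -> bifurcation halving with alveolar
        # uptake withdrawn along each duct
        n_ducts = len(tree.ducts)
        self.q_duct_in = np.zeros((n_ducts, n_steps))
        self.n_alv_on_duct = np.zeros(n_ducts, dtype=np.int64)
        self.class_of_duct_alv = np.zeros(n_ducts, dtype=np.int64)
        for a in tree.alveoli:
            self.n_alv_on_duct[a.duct_index] += 1
            self.class_of_duct_alv[a.duct_index] = a.deformation_class

        # downstream demand per duct (uptake of its own alveoli plus its
        # subtree, plus the attached child unit at terminal ducts); junction
        # flow splits follow the demand so that the audit closes exactly even
        # when sibling ducts carry unequal alveoli counts.  With equal counts
        # this reduces to the symmetric 50/50 split.
        demand = np.zeros((n_ducts, n_steps))
        for u in reversed(tree.units):   # distal units first: child subtree
            child_extra = None           # demand is complete before the parent
            if u.child_unit >= 0:
                child_extra = demand[tree.units[u.child_unit].inlet_duct]
            for didx in reversed(u.duct_indices):
                d = tree.ducts[didx]
                dem = (self.n_alv_on_duct[didx]
                       * self.rate_alv[self.class_of_duct_alv[didx]]).copy()
                if d.children:
                    for c in d.children:
                        dem += demand[c]
                elif child_extra is not None:
                    dem += 2.0 * child_extra  # two outlets, one child copy each
                demand[didx] = dem

        for u in tree.units:
            if u.parent_unit < 0:
                q_unit = sched.q_acinus.copy()
            else:
                # inlet flow = everything this unit and its descendants absorb
                q_unit = demand[u.inlet_duct]
            stack = [(u.inlet_duct, q_unit)]
            while stack:
                didx, q_in = stack.pop()
                self.q_duct_in[didx] = q_in
                d = tree.ducts[didx]
                q_end = (q_in - self.n_alv_on_duct[didx]
                         * self.rate_alv[self.class_of_duct_alv[didx]])
                if d.children:
                    total = sum(demand[c] for c in d.children)
                    for c in d.children:
                        frac = np.where(np.abs(total) > 0,
                                        demand[c] / np.where(total == 0, 1, total),
                                        1.0 / len(d.children))
                        stack.append((c, q_end * frac))

        # upstream mouth count per alveolus (strictly proximal stations)
        n_alv = len(tree.alveoli)
        self.k_upstream = np.zeros(n_alv, dtype=np.int64)
        by_duct: dict[int, list[int]] = {}
        for a in tree.alveoli:
            by_duct.setdefault(a.duct_index, []).append(a.index)
        for didx, members in by_duct.items():
            st = tree.alv_station[members]
            for j, aidx in enumerate(members):
                self.k_upstream[aidx] = int(np.sum(st < st[j] - 1e-12))

        # cavity field coefficients per class and step:
        #   u = dil * rho_vec  +  jet * (1 - (rho/r)^2) * mouth_axis  + vortex
        # dil = dr/dt / r matches the wall-normal speed exactly (the jet and
        # vortex are tangential at the wall); the jet strength matches the
        # neck plug velocity (dV/dt over the mouth area) where the jet enters
        # at the cut plane, so the mouth carries the full alveolar flux and
        # the interior is free of attracting stagnation surfaces.
        f_class = tree.class_f()
        kappa_a = np.array([cap_plane_offset_fraction(f) for f in f_class])
        r = sched.r[:, :-1]                      # class radius at step start
        drdt = sched.drdt
        dvdt = self.rate_alv                     # per alveolus
        nr_class = np.full(4, tree.config.neck_radius_mm * 1e-3)
        nr_class[3] = 0.5 * tree.sac_radius
        self.neck_radius_class = nr_class
        self.plug = dvdt / (math.pi * nr_class[:, None] ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            dil = np.where(r > 0, drdt / r, 0.0)
        self.dil = np.nan_to_num(dil)
        kb2 = 1.0 - kappa_a[:, None] ** 2
        self.jet = (self.plug + kappa_a[:, None] * drdt) / kb2
        self._kappa_a = kappa_a

    # ------------------------------------------------------------------
    def step_index(self, t: float) -> int:
        return self.schedule.step_index(t)

    def duct_flow(self, duct_index: int, s: float, t: float) -> float:
        """Axial flow rate at arclength ``s`` along a duct (signed)."""
        i = self.step_index(t)
        tree = self.tree
        members = np.nonzero(tree.alv_duct == duct_index)[0]
        k = int(np.sum(tree.alv_station[members] < s - 1e-12))
        cls = self.class_of_duct_alv[duct_index]
        return float(self.q_duct_in[duct_index, i] - k * self.rate_alv[cls, i])

    def duct_velocity(self, point, duct_index: int, t: float) -> np.ndarray:
        """Poiseuille velocity at a point inside a duct lumen."""
        d = self.tree.ducts[duct_index]
        p = np.asarray(point, dtype=float)
        rel = p - d.proximal_point
        s = rel @ d.axis
        rho = np.linalg.norm(rel - s * d.axis)
        if rho > d.radius + 1e-12 or not -1e-12 <= s <= d.length + 1e-12:
            raise ValueError("point lies outside the duct lumen")
        q = self.duct_flow(duct_index, s, t)
        u_mean = q / (math.pi * d.radius ** 2)
        return 2.0 * u_mean * (1.0 - (rho / d.radius) ** 2) * d.axis

    def mouth_mean_velocity(self, alv_index: int, t: float) -> float:
        """Signed duct mean velocity at an alveolus mouth station (the shear
        reference for the cavity vortex and the flow-regime ratio)."""
        i = self.step_index(t)
        a = self.tree.alveoli[alv_index]
        cls = a.deformation_class
        q = (self.q_duct_in[a.duct_index, i]
             - self.k_upstream[alv_index] * self.rate_alv[cls, i])
        d = self.tree.ducts[a.duct_index]
        return float(q / (math.pi * d.radius ** 2))

    def alveolar_velocity(self, point, alv_index: int, t: float) -> np.ndarray:
        """Cavity velocity: wall-following dilation + mouth jet + vortex."""
        i = self.step_index(t)
        a = self.tree.alveoli[alv_index]
        cls = a.deformation_class
        r_now = self.schedule.r[cls, i]
        p = np.asarray(point, dtype=float)
        rel = p - a.center
        rho = np.linalg.norm(rel)
        u = (self.dil[cls, i] * rel
             + self.jet[cls, i] * max(1.0 - (rho / r_now) ** 2, 0.0)
             * a.outward_axis)
        if not a.is_sac and self.vortex_strength != 0.0:
            d = self.tree.ducts[a.duct_index]
            u_mouth = self.mouth_mean_velocity(alv_index, t)
            w = np.cross(d.axis, a.outward_axis)
            nw = np.linalg.norm(w)
            if nw > 1e-12:
                w /= nw
                u = u + (self.vortex_strength * u_mouth
                         * (1.0 - (rho / r_now) ** 2) / r_now) * np.cross(w, rel)
        return u

    def neck_velocity(self, point, alv_index: int, t: float) -> np.ndarray:
        """Plug flow through the cylindrical neck (mouth flux / mouth area);
        the capsule reaches one neck radius into the lumen, where the mouth
        jet superposes with the duct profile (the matching band)."""
        i = self.step_index(t)
        a = self.tree.alveoli[alv_index]
        return (self.rate_alv[a.deformation_class, i] / a.mouth_area
                * a.outward_axis)

    def velocity(self, point, t: float) -> np.ndarray:
        """Dispatch by containment: cavity, neck, or duct lumen."""
        p = np.asarray(point, dtype=float)
        tree = self.tree
        i = self.step_index(t)
        best_alv, best_alv_d = -1, -np.inf
        for a in tree.alveoli:
            r_now = self.schedule.r[a.deformation_class, i]
            sd = r_now - np.linalg.norm(p - a.center)
            if sd > best_alv_d:
                best_alv, best_alv_d = a.index, sd
        if best_alv_d > 0:
            return self.alveolar_velocity(p, best_alv, t)
        u = np.zeros(3)
        found = False
        a = tree.alveoli[best_alv] if best_alv >= 0 else None
        if a is not None:
            m0 = a.mouth_point - a.neck_radius * a.outward_axis
            seg = a.center - m0
            seg_len = np.linalg.norm(seg)
            tt = np.clip(((p - m0) @ seg) / seg_len ** 2, 0.0, 1.0)
            if np.linalg.norm(p - (m0 + tt * seg)) <= a.neck_radius:
                u = u + self.neck_velocity(p, best_alv, t)
                found = True
        for d in tree.ducts:
            rel = p - d.proximal_point
            s = rel @ d.axis
            rho = np.linalg.norm(rel - s * d.axis)
            if 0.0 <= s <= d.length and rho <= d.radius:
                u = u + self.duct_velocity(p, d.index, t)
                found = True
                break
        if not found:
            raise ValueError(f"point {p} lies outside the air domain")
        return u

    def flow_regime_ratio(self, alv_index: int, t: float) -> float:
        """|mouth flux| / (|duct mean velocity| x mouth area); larger means
        the cavity flow is more radial, smaller means shear-driven
        recirculation dominates."""
        i = self.step_index(t)
        a = self.tree.alveoli[alv_index]
        flux = abs(self.rate_alv[a.deformation_class, i])
        if flux == 0.0:
            return 0.0
        shear = abs(self.mouth_mean_velocity(alv_index, t)) * a.mouth_area
        if shear <= flux / REGIME_RATIO_SENTINEL:
            return REGIME_RATIO_SENTINEL
        return float(flux / shear)

    def regime_ratio_by_generation(self, t: float) -> dict[int, float]:
        """Mean flow-regime ratio over the alveoli of each generation."""
        out: dict[int, list[float]] = {}
        for a in self.tree.alveoli:
            out.setdefault(a.generation, []).append(
                self.flow_regime_ratio(a.index, t))
        return {g: float(np.mean(v)) for g, v in sorted(out.items())}

    def mass_audit(self, t: float) -> float:
        """Worst relative imbalance over all ducts: flow in vs children out
        plus alveolar mouth fluxes."""
        i = self.step_index(t)
        worst = 0.0
        tree = self.tree
        for d in tree.ducts:
            q_in = self.q_duct_in[d.index, i]
            cls = self.class_of_duct_alv[d.index]
            uptake = self.n_alv_on_duct[d.index] * self.rate_alv[cls, i]
            if d.children:
                q_out = sum(self.q_duct_in[c, i] for c in d.children)
            else:
                u = tree.units[d.unit_index]
                if u.child_unit >= 0:
                    # both outlet branches carry the resolved child's inlet flow
                    child = tree.units[u.child_unit]
                    q_out = 2.0 * self.q_duct_in[child.inlet_duct, i]
                else:
                    q_out = 0.0  # sac-terminated: uptake absorbs the flow
            scale = max(abs(q_in), 1e-30)
            worst = max(worst, abs(q_in - uptake - q_out) / scale)
        return worst
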