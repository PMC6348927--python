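"""Parametric acinar tree: bifurcating alveolar ducts with partial-spheroid
alveoli.

The acinus (generations 16-23) is represented by three resolved units:

* ``TBU_16_18`` - a triple bifurcation unit for the partially alveolated
  respiratory bronchioles (one resolved copy, multiplicity 1, 84 alveoli);
* ``TBU_19_21`` - a triple bifurcation unit for the fully alveolated ducts
  (one resolved copy standing for 8 parallel units, 182 alveoli);
* ``DBU_22_23`` - a double bifurcation unit (one resolved copy standing for
  64 units) carrying 25 alveoli on the generation-22 duct and 4 terminal
  quasi-spherical sacs, each sac conserving the volume of a generation-23
  duct with 17 alveoli.

Each alveolus is a 3/4 partial spheroid (fractional volume f = 0.75; the
sacs use f = 0.97) anchored to the duct surface through a cylindrical neck.
Alveoli are laid out on seeded ring lattices around each duct and the whole
unit is checked for a minimum pairwise surface gap, the septal clearance.

Units live in their own local frames (inlet duct along local +x, bifurcation
plane x-y); the frame rotation of each unit relative to the laboratory frame
(where gravity is -z) is stored so that particle transport sees a
consistently oriented gravity vector.  Consecutive units are rotated about
the connecting axis by a configurable angle (default 90 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .config import GeometryConfig

MM = 1e-3  # config lengths are mm; internal lengths are metres

#: deformation classes: alveoli share a wall-motion schedule within a class
CLASS_NAMES = ("16_18", "19_21", "22", "23")
CLASS_OF_GENERATION = {16: 0, 17: 0, 18: 0, 19: 1, 20: 1, 21: 1, 22: 2, 23: 3}
REGION_OF_GENERATION = {16: "proximal", 17: "proximal", 18: "proximal",
                        19: "mid", 20: "mid", 21: "mid",
                        22: "distal", 23: "distal"}


class GeometryError(RuntimeError):
    """Raised when the requested alveolar density cannot be placed."""


def alveolus_volume(radius: float, f: float) -> float:
    """Volume of a partial-spheroid alveolus, ``f * (4/3) * pi * r**3``.

    ``f`` is the fractional volume of the spherical cap solid (0.75 for a
    3/4-spheroid alveolus, 0.97 for a nearly closed terminal sac).
    """
    if radius < 0:
        raise ValueError(f"alveolus radius must be non-negative, got {radius}")
    if not 0 < f <= 1:
        raise ValueError(f"fractional volume must lie in (0, 1], got {f}")
    return f * (4.0 / 3.0) * math.pi * radius ** 3


def cap_plane_offset_fraction(f: float) -> float:
    """Distance (in units of the radius) from the sphere centre to the cut
    plane of a partial spheroid retaining volume fraction ``f``.

    The removed cap of height ``c`` satisfies ``c^2 (3r - c)/4r^3 = 1 - f``;
    the plane sits at ``a = r - c`` on the mouth side of the centre.
    """
    if not 0 < f <= 1:
        raise ValueError("f must lie in (0, 1]")
    if f == 1.0:
        return -1.0  # full sphere: the 'plane' degenerates to the far pole

    def g(c: float) -> float:
        return c * c * (3.0 - c) - 4.0 * (1.0 - f)

    c = brentq(g, 0.0, 2.0, xtol=1e-15)
    return 1.0 - c


def whole_lung_alveoli(acinus_count: int, per_acinus: int) -> int:
    """Total alveoli in a symmetric lung of ``acinus_count`` identical acini."""
    if acinus_count < 0 or per_acinus < 0:
        raise ValueError("counts must be non-negative")
    return int(acinus_count) * int(per_acinus)


@dataclass
class DuctSpec:
    """One rigid cylindrical duct segment, in its unit's local frame."""

    index: int                 # global index within the tree
    generation: int
    diameter: float            # m
    length: float              # m
    proximal_point: np.ndarray
    axis: np.ndarray           # unit vector
    n1: np.ndarray             # radial basis completing (axis, n1, n2)
    n2: np.ndarray
    unit_index: int
    parent: int = -1           # duct index, -1 for a unit inlet duct
    children: list[int] = field(default_factory=list)
    branch_dirs: list[np.ndarray] = field(default_factory=list)  # outlet axes

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def distal_point(self) -> np.ndarray:
        return self.proximal_point + self.length * self.axis


@dataclass
class AlveolusSpec:
    """One partial-spheroid alveolus (or terminal sac) on a duct surface."""

    index: int
    generation: int
    unit_index: int
    duct_index: int
    radius: float              # FRC radius AR (m); sacs use their own radius
    neck_radius: float
    depth: float               # mouth-to-floor depth D (m)
    f: float                   # fractional volume (0.75 alveolus, 0.97 sac)
    center: np.ndarray         # local frame
    mouth_point: np.ndarray    # anchor on the duct surface (or duct end cap)
    outward_axis: np.ndarray   # unit vector, duct surface -> cavity centre
    axial_station: float       # arclength s of the mouth along the duct
    is_sac: bool = False

    @property
    def deformation_class(self) -> int:
        return CLASS_OF_GENERATION[self.generation]

    @property
    def frc_volume(self) -> float:
        return alveolus_volume(self.radius, self.f)

    @property
    def mouth_area(self) -> float:
        return math.pi * self.neck_radius ** 2


@dataclass
class AcinarUnit:
    """A resolved bifurcation unit plus the multiplicity it stands for."""

    index: int
    unit_id: str                       # TBU_16_18 | TBU_19_21 | DBU_22_23 | ...
    generations: tuple[int, ...]
    duct_indices: list[int]
    alveolus_indices: list[int]
    multiplicity: int
    alveoli_count_target: int
    alveolar_volume_fraction: float    # whole-acinus fraction of this unit
    class_fractions: dict[int, float]  # deformation class -> acinus fraction
    rotation: np.ndarray               # local -> laboratory frame (3x3)
    inlet_duct: int
    outlet_ducts: list[int]            # terminal ducts carrying outlet planes
    parent_unit: int = -1
    child_unit: int = -1

    @property
    def gravity_local(self) -> np.ndarray:
        """Unit vector of gravity expressed in this unit's local frame."""
        return self.rotation.T @ np.array([0.0, 0.0, -1.0])


@dataclass
class AcinarTree:
    """The resolved acinus: units, ducts, alveoli and packed arrays."""

    config: GeometryConfig
    units: list[AcinarUnit]
    ducts: list[DuctSpec]
    alveoli: list[AlveolusSpec]
    rng_seed: int
    sac_radius: float                  # FRC radius of a terminal sac (m)

    # packed arrays (filled by _pack)
    alv_center: np.ndarray = field(default=None, repr=False)
    alv_r0: np.ndarray = field(default=None, repr=False)
    alv_class: np.ndarray = field(default=None, repr=False)
    alv_unit: np.ndarray = field(default=None, repr=False)
    alv_duct: np.ndarray = field(default=None, repr=False)
    alv_gen: np.ndarray = field(default=None, repr=False)
    alv_station: np.ndarray = field(default=None, repr=False)
    _unit_trees: dict[int, cKDTree] = field(default_factory=dict, repr=False)

    def _pack(self) -> None:
        self.alv_center = np.array([a.center for a in self.alveoli]).reshape(-1, 3)
        self.alv_r0 = np.array([a.radius for a in self.alveoli])
        self.alv_class = np.array([a.deformation_class for a in self.alveoli], dtype=np.int64)
        self.alv_unit = np.array([a.unit_index for a in self.alveoli], dtype=np.int64)
        self.alv_duct = np.array([a.duct_index for a in self.alveoli], dtype=np.int64)
        self.alv_gen = np.array([a.generation for a in self.alveoli], dtype=np.int64)
        self.alv_station = np.array([a.axial_station for a in self.alveoli])
        self._unit_trees = {}
        for u in self.units:
            idx = np.array(u.alveolus_indices, dtype=np.int64)
            if idx.size:
                self._unit_trees[u.index] = cKDTree(self.alv_center[idx])

    def unit_alveoli(self, unit_index: int) -> np.ndarray:
        return np.array(self.units[unit_index].alveolus_indices, dtype=np.int64)

    def unit_kdtree(self, unit_index: int) -> Optional[cKDTree]:
        return self._unit_trees.get(unit_index)

    @property
    def connectivity(self) -> dict[str, str]:
        out = {}
        for u in self.units:
            if u.child_unit >= 0:
                out[u.unit_id] = self.units[u.child_unit].unit_id
        return out

    # ------------------------------------------------------------------
    def class_counts(self) -> np.ndarray:
        """Number of alveoli per deformation class in the resolved units."""
        n = np.zeros(4, dtype=np.int64)
        for a in self.alveoli:
            n[a.deformation_class] += 1
        return n

    def class_mult(self) -> np.ndarray:
        m = np.ones(4, dtype=np.int64)
        for u in self.units:
            for c in u.class_fractions:
                m[c] = u.multiplicity
        return m

    def class_fractions(self) -> np.ndarray:
        f = np.zeros(4)
        for u in self.units:
            for c, v in u.class_fractions.items():
                f[c] = v
        return f

    def class_frc_radii(self) -> np.ndarray:
        r = np.full(4, self.config.alveolus_radius_mm * MM)
        r[3] = self.sac_radius
        return r

    def class_f(self) -> np.ndarray:
        return np.array([self.config.f_alveolus] * 3 + [self.config.f_sac])


# ----------------------------------------------------------------------
# construction helpers

def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    return (v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c))


def _radial_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.99:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = np.cross(ref, axis)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(axis, n1)
    return n1, n2


def _unit_frame(parent_rotation: np.ndarray, inlet_axis_global: np.ndarray,
                rotation_deg: float) -> np.ndarray:
    """Orthonormal local->lab frame for a unit whose inlet axis is given in
    laboratory coordinates; the bifurcation plane normal is the parent's
    normal rotated about the inlet axis."""
    x = inlet_axis_global / np.linalg.norm(inlet_axis_global)
    n_parent = parent_rotation @ np.array([0.0, 0.0, 1.0])
    n0 = n_parent - (n_parent @ x) * x
    if np.linalg.norm(n0) < 1e-9:
        n0 = parent_rotation @ np.array([0.0, 1.0, 0.0])
        n0 = n0 - (n0 @ x) * x
    n0 /= np.linalg.norm(n0)
    n = _rotate_about(n0, x, math.radians(rotation_deg))
    y = np.cross(n, x)
    return np.column_stack([x, y, n])


def _duct_lattice_sites(duct: DuctSpec, cfg: GeometryConfig,
                        prox_margin: float, distal_margin: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Candidate alveolus centres on seeded rings around a duct.

    Returns an array of rows (s, phi, cx, cy, cz).  Ring lattices (evenly
    spaced mouths per ring, hexagonal axial offset, random azimuthal phase)
    reach the near-close-packed surface density the model's alveoli counts
    demand, which uniform rejection sampling cannot.
    """
    ar = cfg.alveolus_radius_mm * MM
    gap = cfg.septal_gap_mm * MM
    offset = (cfg.alveolus_depth_mm - cfg.alveolus_radius_mm) * MM
    # 0.5% inflation keeps lattice neighbours strictly clear of the required
    # distance instead of exactly on it (float-robust)
    spacing = (2.0 * ar + gap) * 1.005
    rc = duct.radius + offset
    half = spacing / (2.0 * rc)
    if half >= 1.0:
        n_ring = 1
    else:
        n_ring = max(1, int(2.0 * math.pi // (2.0 * math.asin(half))))
    dphi = 2.0 * math.pi / n_ring
    c_off = 2.0 * rc * math.sin(dphi / 4.0)
    dz = math.sqrt(max(spacing ** 2 - c_off ** 2, 0.0)) or spacing

    rows = []
    s = prox_margin
    k = 0
    phase = rng.uniform(0.0, 2.0 * math.pi)  # one phase per duct: rings keep
    while s <= duct.length - distal_margin + 1e-12:  # their hex half-offset
        for j in range(n_ring):
            phi = phase + (j + 0.5 * (k % 2)) * dphi
            center = (duct.proximal_point + s * duct.axis
                      + rc * (math.cos(phi) * duct.n1 + math.sin(phi) * duct.n2))
            rows.append((s, phi, *center))
        s += dz
        k += 1
    return np.array(rows).reshape(-1, 5)


def _sac_radius(cfg: GeometryConfig) -> float:
    """FRC radius of a terminal sac conserving the volume of a generation-23
    duct together with its equivalent count of discrete alveoli."""
    l23, d23 = cfg.duct_table_mm[23]
    v_duct = math.pi * (0.5 * d23 * MM * cfg.duct_scale) ** 2 * (l23 * MM * cfg.duct_scale)
    v_alv = alveolus_volume(cfg.alveolus_radius_mm * MM, cfg.f_alveolus)
    v_sac = v_duct + cfg.sac_equivalent_alveoli * v_alv
    return (v_sac / (cfg.f_sac * 4.0 / 3.0 * math.pi)) ** (1.0 / 3.0)


_UNIT_PLANS = {
    "TBU_16_18": dict(generations=(16, 17, 18), multiplicity=1, sacs=False),
    "TBU_19_21": dict(generations=(19, 20, 21), multiplicity=8, sacs=False),
    "DBU_22_23": dict(generations=(22, 23), multiplicity=64, sacs=True),
    # single-duct fixture unit used by the test suite
    "SINGLE_16": dict(generations=(16,), multiplicity=1, sacs=False),
}
DEFAULT_UNIT_ORDER = ("TBU_16_18", "TBU_19_21", "DBU_22_23")


def build_acinus(config: GeometryConfig,
                 units: Sequence[str] = DEFAULT_UNIT_ORDER) -> AcinarTree:
    """Assemble the resolved acinar tree from the configuration.

    Raises :class:`GeometryError` if the requested alveolar density cannot be
    placed with the configured septal gap.
    """
    rng = np.random.default_rng(config.seed)
    cfg = config
    scale = cfg.duct_scale

    ducts: list[DuctSpec] = []
    alveoli: list[AlveolusSpec] = []
    unit_objs: list[AcinarUnit] = []
    sac_r = _sac_radius(cfg)
    half_angle = math.radians(cfg.branch_half_angle_deg)

    prev_rotation = np.eye(3)
    prev_outlet_axis_local: Optional[np.ndarray] = None

    for ui, unit_id in enumerate(units):
        plan = _UNIT_PLANS[unit_id]
        gens = plan["generations"]

        # ---- duct skeleton (unit local frame: inlet along +x, plane x-y)
        unit_duct_idx: list[int] = []
        level_ducts: list[list[int]] = []
        for level, gen in enumerate(gens):
            l_mm, d_mm = cfg.duct_table_mm[gen]
            length, diameter = l_mm * MM * scale, d_mm * MM * scale
            this_level: list[int] = []
            if level == 0:
                axis = np.array([1.0, 0.0, 0.0])
                n1, n2 = _radial_basis(axis)
                d = DuctSpec(len(ducts), gen, diameter, length,
                             np.zeros(3), axis, n1, n2, ui)
                ducts.append(d)
                this_level.append(d.index)
            else:
                for pidx in level_ducts[level - 1]:
                    parent = ducts[pidx]
                    for sgn in (+1, -1):
                        axis = _rotate_about(parent.axis, np.array([0.0, 0.0, 1.0]),
                                             sgn * half_angle)
                        n1, n2 = _radial_basis(axis)
                        d = DuctSpec(len(ducts), gen, diameter, length,
                                     parent.distal_point.copy(), axis, n1, n2,
                                     ui, parent=parent.index)
                        parent.children.append(d.index)
                        ducts.append(d)
                        this_level.append(d.index)
            level_ducts.append(this_level)
            unit_duct_idx.extend(this_level)

        # outlet branch directions on the terminal ducts
        terminal = level_ducts[-1]
        for tidx in terminal:
            td = ducts[tidx]
            if not plan["sacs"]:
                for sgn in (+1, -1):
                    td.branch_dirs.append(
                        _rotate_about(td.axis, np.array([0.0, 0.0, 1.0]),
                                      sgn * half_angle))

        # ---- unit frame relative to the laboratory
        if ui == 0:
            rotation = np.eye(3)
        else:
            inlet_axis_global = prev_rotation @ prev_outlet_axis_local
            rotation = _unit_frame(prev_rotation, inlet_axis_global,
                                   cfg.inter_unit_rotation_deg)

        # ---- alveolus placement (ring lattice + global septal-gap check)
        targets = {g: cfg.alveoli_per_generation.get(g, 0) for g in gens
                   if not (plan["sacs"] and g == gens[-1])}
        placed = _place_unit_alveoli(cfg, ducts, level_ducts, gens, targets,
                                     plan, unit_id, ui, rng, len(alveoli), sac_r)
        alveoli.extend(placed)

        # ---- bookkeeping
        if unit_id == "TBU_16_18":
            class_fr = {0: cfg.alveolar_volume_fractions["16_18"]}
        elif unit_id == "TBU_19_21":
            class_fr = {1: cfg.alveolar_volume_fractions["19_21"]}
        elif unit_id == "DBU_22_23":
            class_fr = {2: cfg.alveolar_volume_fractions["22"],
                        3: cfg.alveolar_volume_fractions["23"]}
        else:  # fixture units reuse the class of their generations
            class_fr = {CLASS_OF_GENERATION[gens[0]]: 1.0}

        unit = AcinarUnit(
            index=ui, unit_id=unit_id, generations=tuple(gens),
            duct_indices=unit_duct_idx,
            alveolus_indices=[a.index for a in placed],
            multiplicity=plan["multiplicity"],
            alveoli_count_target=sum(targets.values()) + (cfg.sacs_per_dbu if plan["sacs"] else 0),
            alveolar_volume_fraction=float(sum(class_fr.values())),
            class_fractions=class_fr,
            rotation=rotation,
            inlet_duct=level_ducts[0][0],
            outlet_ducts=list(terminal),
        )
        if ui > 0:
            unit.parent_unit = ui - 1
            unit_objs[ui - 1].child_unit = ui
        unit_objs.append(unit)

        prev_rotation = rotation
        if ducts[terminal[0]].branch_dirs:
            prev_outlet_axis_local = ducts[terminal[0]].branch_dirs[0]
        else:
            prev_outlet_axis_local = ducts[terminal[0]].axis

    tree = AcinarTree(config=cfg, units=unit_objs, ducts=ducts,
                      alveoli=alveoli, rng_seed=cfg.seed, sac_radius=sac_r)
    tree._pack()
    _check_septal_gaps(tree)
    return tree


def _place_unit_alveoli(cfg, ducts, level_ducts, gens, targets, plan, unit_id,
                        ui, rng, base_index, sac_r) -> list[AlveolusSpec]:
    """Greedy seeded placement of one unit's alveoli and sacs."""
    ar = cfg.alveolus_radius_mm * MM
    nr = cfg.neck_radius_mm * MM
    depth = cfg.alveolus_depth_mm * MM
    gap = cfg.septal_gap_mm * MM

    gen_ducts = {g: level_ducts[gens.index(g)] for g in targets}
    gen_has_children = {
        g: any(targets.get(gens[lvl + 1], 0) > 0
               for lvl in [gens.index(g)] if lvl + 1 < len(gens))
        for g in targets}

    # sacs first: deterministic out-of-plane positions at the terminal ducts
    sac_specs: list[tuple] = []
    if plan["sacs"]:
        fwd = 0.20 * MM
        lat = sac_r + 0.5 * gap + 0.03 * MM
        zhat = np.array([0.0, 0.0, 1.0])
        for tidx in level_ducts[-1]:
            td = ducts[tidx]
            for sgn in (+1, -1):
                center = td.distal_point + fwd * td.axis + sgn * lat * zhat
                sac_specs.append((tidx, center))
        if len(sac_specs) != cfg.sacs_per_dbu:
            # target sac count must match 2 per terminal duct
            raise GeometryError(
                f"{unit_id}: {cfg.sacs_per_dbu} sacs requested but the unit "
                f"provides {len(sac_specs)} terminal attachment points")

    for attempt in range(cfg.placement_max_attempts):
        accepted_centers: list[np.ndarray] = []
        accepted_radii: list[float] = []
        accepted_meta: list[tuple] = []
        ok = True

        for (tidx, center) in sac_specs:
            accepted_centers.append(center)
            accepted_radii.append(sac_r)
            accepted_meta.append(("sac", tidx, center))

        # lattice sites pooled per generation; sibling sleeves interpenetrate
        # near bifurcations, so a generation's alveoli are placed jointly
        # across its ducts, tightest generation first
        gen_sites: dict[int, list[tuple[int, np.ndarray]]] = {}
        for g, dlist in gen_ducts.items():
            if targets[g] == 0:
                continue
            pool: list[tuple[int, np.ndarray]] = []
            for didx in dlist:
                duct = ducts[didx]
                is_inlet = duct.parent == -1
                prox = (cfg.inlet_margin_mm if is_inlet else cfg.child_margin_mm) * MM
                dist = (cfg.parent_distal_margin_mm
                        if (gen_has_children[g] and duct.children)
                        else cfg.distal_margin_mm) * MM
                for row in _duct_lattice_sites(duct, cfg, prox, dist, rng):
                    pool.append((didx, row))
            gen_sites[g] = pool
        order = sorted(gen_sites, key=lambda g: -(
            targets[g] / max(len(gen_sites[g]), 1)))
        failed_gen = None
        for g in order:
            pool = gen_sites[g]
            if len(pool) < targets[g]:
                ok, failed_gen = False, g
                break
            n_got = 0
            for j in rng.permutation(len(pool)):
                if n_got == targets[g]:
                    break
                didx, row = pool[j]
                c = row[2:5]
                if accepted_centers:
                    d2 = np.linalg.norm(np.asarray(accepted_centers) - c, axis=1)
                    req = np.asarray(accepted_radii) + ar + gap
                    if np.any(d2 < req):
                        continue
                accepted_centers.append(c)
                accepted_radii.append(ar)
                accepted_meta.append(("alv", didx, row))
                n_got += 1
            if n_got < targets[g]:
                ok, failed_gen = False, g
                break
        if ok:
            break
    else:
        ok = False
    if not ok:
        raise GeometryError(
            f"could not place {targets.get(failed_gen, '?')} alveoli on the "
            f"generation-{failed_gen} ducts of {unit_id} with septal gap "
            f"{cfg.septal_gap_mm} mm after {cfg.placement_max_attempts} attempts")

    specs: list[AlveolusSpec] = []
    for kind, didx, payload in accepted_meta:
        duct = ducts[didx]
        if kind == "sac":
            center = payload
            outward = center - duct.distal_point
            outward = outward / np.linalg.norm(outward)
            specs.append(AlveolusSpec(
                index=base_index + len(specs), generation=gens[-1],
                unit_index=ui, duct_index=didx, radius=sac_r,
                neck_radius=0.5 * sac_r, depth=2.0 * sac_r, f=cfg.f_sac,
                center=center, mouth_point=duct.distal_point.copy(),
                outward_axis=outward, axial_station=duct.length, is_sac=True))
        else:
            s, phi = payload[0], payload[1]
            center = payload[2:5]
            outward = (math.cos(phi) * duct.n1 + math.sin(phi) * duct.n2)
            mouth = duct.proximal_point + s * duct.axis + duct.radius * outward
            specs.append(AlveolusSpec(
                index=base_index + len(specs), generation=duct.generation,
                unit_index=ui, duct_index=didx, radius=ar, neck_radius=nr,
                depth=depth, f=cfg.f_alveolus, center=np.asarray(center),
                mouth_point=mouth, outward_axis=outward, axial_station=s))
    return specs


def _check_septal_gaps(tree: AcinarTree) -> None:
    """Verify the minimum pairwise surface gap within each unit."""
    gap = tree.config.septal_gap_mm * MM
    for u in tree.units:
        idx = tree.unit_alveoli(u.index)
        if idx.size < 2:
            continue
        centers = tree.alv_center[idx]
        radii = tree.alv_r0[idx]
        kdt = cKDTree(centers)
        pairs = kdt.query_pairs(r=2.0 * radii.max() + gap, output_type="ndarray")
        if pairs.size == 0:
            continue
        d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
        req = radii[pairs[:, 0]] + radii[pairs[:, 1]] + gap
        if np.any(d < req - 1e-12):
            k = int(np.argmin(d - req))
            raise GeometryError(
                f"septal gap violated in {u.unit_id}: alveoli pair "
                f"{tuple(idx[pairs[k]])} gap {(d[k] - req[k] + gap) / MM:.4f} mm")


# ----------------------------------------------------------------------
# queries

def count_alveoli(tree: AcinarTree, expand_sacs: bool = False) -> int:
    """Total alveoli across the acinus, weighting each resolved unit by its
    multiplicity; with ``expand_sacs`` each terminal sac counts as the number
    of discrete alveoli it stands for (17 by default)."""
    total = 0
    eq = tree.config.sac_equivalent_alveoli
    for u in tree.units:
        n_alv = sum(1 for i in u.alveolus_indices if not tree.alveoli[i].is_sac)
        n_sac = sum(1 for i in u.alveolus_indices if tree.alveoli[i].is_sac)
        per_unit = n_alv + n_sac * (eq if expand_sacs else 1)
        total += u.multiplicity * per_unit
    return total


def nearest_wall(point, tree: AcinarTree, unit: Optional[int] = None,
                 class_radii: Optional[np.ndarray] = None):
    """Signed distance from ``point`` to the nearest air-domain surface.

    Positive inside the air domain, negative outside.  Returns
    ``(distance, surface_id)`` with ``surface_id = (kind, unit, index,
    generation)``.  ``class_radii`` supplies instantaneous alveolar radii per
    deformation class (defaults to FRC).  Points far outside every unit's
    bounding region raise ``LookupError``.
    """
    p = np.asarray(point, dtype=float)
    radii = tree.class_frc_radii() if class_radii is None else np.asarray(class_radii)
    units = [tree.units[unit]] if unit is not None else tree.units
    best = (-np.inf, None)
    for u in units:
        # ducts: open-ended cylinders (junction and outlet planes are open)
        for didx in u.duct_indices:
            d = tree.ducts[didx]
            rel = p - d.proximal_point
            s = rel @ d.axis
            rho = np.linalg.norm(rel - s * d.axis)
            if -d.radius <= s <= d.length + d.radius:
                sd = d.radius - rho
                if not (0.0 <= s <= d.length):
                    sd = min(sd, -abs(s if s < 0 else s - d.length))
                if sd > best[0]:
                    best = (sd, ("duct", u.index, didx, d.generation))
        # alveolar cavities and necks
        for aidx in u.alveolus_indices:
            a = tree.alveoli[aidx]
            r_now = radii[a.deformation_class]
            sd = r_now - np.linalg.norm(p - a.center)
            seg = a.center - a.mouth_point
            seg_len = np.linalg.norm(seg)
            if seg_len > 0:
                t = np.clip(((p - a.mouth_point) @ seg) / seg_len ** 2, 0.0, 1.0)
                sd_neck = a.neck_radius - np.linalg.norm(p - (a.mouth_point + t * seg))
                sd = max(sd, sd_neck)
            if sd > best[0]:
                best = (sd, ("alveolus", u.index, aidx, a.generation))
    if best[1] is None or best[0] < -5e-3:
        raise LookupError(f"point {p} is far outside the acinar air domain")
    return best


def morphometry_frame(tree: AcinarTree) -> pd.DataFrame:
    """Per-generation morphometry: duct counts, alveoli, dimensions, volume."""
    rows = []
    for gen in sorted({d.generation for d in tree.ducts}):
        dd = [d for d in tree.ducts if d.generation == gen]
        mult = tree.units[dd[0].unit_index].multiplicity
        alv = [a for a in tree.alveoli if a.generation == gen]
        v_ml = sum(a.frc_volume for a in alv) * mult * 1e6
        rows.append(dict(
            generation=gen,
            n_ducts=len(dd) * mult,
            n_alveoli=len(alv) * mult,
            duct_diameter_mm=dd[0].diameter / MM,
            duct_length_mm=dd[0].length / MM,
            alveolar_volume_ml=v_ml,
        ))
    return pd.DataFrame(rows)


def export_surface(tree: AcinarTree, path: str) -> None:
    """Write the tree surface (per-primitive watertight meshes) as STL."""
    import trimesh

    meshes = []
    for u in tree.units:
        R, _t = u.rotation, np.zeros(3)
        for didx in u.duct_indices:
            d = tree.ducts[didx]
            cyl = trimesh.creation.cylinder(radius=d.radius, height=d.length,
                                            sections=24)
            # cylinder() is centred on the origin along z: move to the duct
            z = np.array([0.0, 0.0, 1.0])
            T = np.eye(4)
            T[:3, :3] = R @ _align(z, d.axis)
            T[:3, 3] = R @ (d.proximal_point + 0.5 * d.length * d.axis)
            cyl.apply_transform(T)
            meshes.append(cyl)
        for aidx in u.alveolus_indices:
            a = tree.alveoli[aidx]
            sph = trimesh.creation.icosphere(subdivisions=2, radius=a.radius)
            T = np.eye(4)
            T[:3, :3] = R
            T[:3, 3] = R @ a.center
            sph.apply_transform(T)
            meshes.append(sph)
    scene = trimesh.util.concatenate(meshes)
    scene.export(path)


def _align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)
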