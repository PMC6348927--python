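"""Breathing-driven alveolar wall kinematics.

A constant-flow breathing waveform (oral scale) is divided down to the
generation-16 acinus inlet through the symmetric-dichotomy rule
``Q_g = Q_inlet / 2**g`` and partitioned between the four deformation
classes (TBU 16-18, TBU 19-21, generation-22 alveoli, generation-23 sacs)
in proportion to their alveolar volume fractions (0.03 / 0.25 / 0.27 /
0.45 by default).  Each class's volume rate, divided by its alveoli count,
drives the isotropic balloon expansion of its alveoli through the exact
cubic relation

    dV = f * (4/3) * pi * ((r + dr)**3 - r**3)

Two compliance rules shape the trajectory:

* strain stiffening - once the cumulative inhaled (oral) volume passes a
  threshold (500 ml default), the expansion rate of the non-terminal
  classes is multiplied by a stiffening factor (0.5) and the displaced
  flow is redistributed to the generation-23 sacs;
* expansion cap - no alveolus may exceed ``(1 + cap) * r_FRC`` with
  ``cap = (TLC/FRC)**(1/3) - 1`` (0.26 for 3000/6000 ml); a capped class's
  residual demand is likewise redistributed to the sacs.

Exhalation retraces the inhalation radius path in reverse at a rate scaled
by the inhale/exhale duration ratio, so every cycle closes exactly on the
FRC radii (no geometric hysteresis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import AcinarTree, CLASS_NAMES

LPM_TO_M3S = 1e-3 / 60.0
ML_TO_M3 = 1e-6


class ConservationError(RuntimeError):
    """Raised when redistribution cannot satisfy the required inlet flow."""


@dataclass
class BreathingWaveform:
    """Constant-flow square waveform at the oral inlet.

    ``q_inlet_lpm`` is the oral inhalation flow rate; exhalation runs the
    reverse path, by default over the same duration.
    """

    q_inlet_lpm: float = 15.0
    inhale_s: float = 2.0
    exhale_s: Optional[float] = None
    tidal_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if self.exhale_s is None:
            self.exhale_s = self.inhale_s
        implied = self.q_inlet_lpm * LPM_TO_M3S * self.inhale_s / ML_TO_M3
        if self.tidal_ml is None:
            self.tidal_ml = implied
        elif abs(self.tidal_ml - implied) > 1e-9 * max(implied, 1.0):
            raise ValueError(
                f"tidal volume {self.tidal_ml} ml != flow x inhale duration "
                f"({implied} ml)")

    @property
    def period_s(self) -> float:
        return self.inhale_s + self.exhale_s

    def q_oral(self, t: float) -> float:
        """Signed oral flow rate (m^3/s); positive during inhalation."""
        if 0.0 <= t < self.inhale_s:
            return self.q_inlet_lpm * LPM_TO_M3S
        if self.inhale_s <= t <= self.period_s:
            return -self.q_inlet_lpm * LPM_TO_M3S * self.inhale_s / self.exhale_s
        return 0.0


@dataclass
class ComplianceRule:
    """Strain-stiffening and expansion-cap parameters."""

    stiffening_threshold_ml: float = 500.0
    stiffening_factor: float = 0.5
    cap_factor: Optional[float] = None   # None -> (TLC/FRC)^(1/3) - 1
    redistribution_class: int = 3        # generation-23 sacs

    def __post_init__(self) -> None:
        if not 0 < self.stiffening_factor <= 1:
            raise ValueError("stiffening factor must lie in (0, 1]")
        if self.cap_factor is not None and self.cap_factor <= 0:
            raise ValueError("cap factor must be positive")


def radius_increment(r: float, dV: float, f: float) -> float:
    """Exact radius change of a partial spheroid absorbing volume ``dV``.

    Solves ``dV = f*(4/3)*pi*((r+dr)^3 - r^3)`` in closed form; ``dr`` is
    negative for contraction.  Contraction beyond the current volume is a
    domain error.
    """
    if r < 0 or not 0 < f <= 1:
        raise ValueError("need r >= 0 and f in (0, 1]")
    if dV == 0.0:
        return 0.0
    v_new = f * (4.0 / 3.0) * math.pi * r ** 3 + dV
    if v_new <= 0:
        raise ValueError(
            f"contraction dV={dV} exceeds the current alveolus volume")
    return (r ** 3 + 3.0 * dV / (4.0 * math.pi * f)) ** (1.0 / 3.0) - r


def max_expansion_factor(frc_ml: float, tlc_ml: float) -> float:
    """Maximum fractional radius increase under self-similar inflation,
    ``(TLC/FRC)**(1/3) - 1``."""
    if not tlc_ml >= frc_ml > 0:
        raise ValueError("need TLC >= FRC > 0")
    return (tlc_ml / frc_ml) ** (1.0 / 3.0) - 1.0


def generation_flow(q_inlet: float, generation: int) -> float:
    """Flow through one airway of generation ``g`` in a symmetric
    dichotomous tree: ``Q_inlet / 2**g``."""
    if generation < 0:
        raise ValueError("generation must be non-negative")
    return q_inlet / 2.0 ** generation


def unit_volume_rate(q_inlet: float, unit) -> float:
    """Volume rate of one resolved unit: inlet flow times the unit's
    whole-acinus alveolar volume fraction, divided by its multiplicity."""
    fraction = unit.alveolar_volume_fraction
    return q_inlet * fraction / unit.multiplicity


@dataclass
class WallMotionSchedule:
    """Per-class alveolar radius trajectories over one breathing cycle.

    Arrays are sampled on a uniform grid of ``n_steps`` intervals covering
    inhalation followed by exhalation.  ``rate_acinus`` holds the realised
    (post-compliance) acinus-scale volume rate of each class, signed.
    """

    tree: AcinarTree
    waveform: BreathingWaveform
    rule: ComplianceRule
    dt: float
    t: np.ndarray                 # (n_steps + 1,) node times
    r: np.ndarray                 # (4, n_steps + 1) class radii (m)
    drdt: np.ndarray              # (4, n_steps) interval rates (m/s)
    rate_acinus: np.ndarray       # (4, n_steps) class volume rates (m^3/s)
    q_acinus: np.ndarray          # (n_steps,) acinus inlet flow (m^3/s)
    cumulative_ml: np.ndarray     # (n_steps + 1,) oral inhaled volume
    stiffened: np.ndarray         # (n_steps,) bool
    capped: np.ndarray            # (4, n_steps) bool
    n_inhale: int = 0
    class_counts: np.ndarray = field(default=None)
    class_mult: np.ndarray = field(default=None)

    @property
    def n_steps(self) -> int:
        return self.t.size - 1

    def step_index(self, t: float) -> int:
        i = int(np.searchsorted(self.t, t, side="right")) - 1
        return min(max(i, 0), self.n_steps - 1)

    def radius(self, cls: int, t: float) -> float:
        """Class radius at time ``t`` (linear within a step)."""
        return float(self.radii_at(t)[cls])

    def radii_at(self, t: float) -> np.ndarray:
        i = self.step_index(t)
        w = np.clip((t - self.t[i]) / (self.t[i + 1] - self.t[i]), 0.0, 1.0)
        return self.r[:, i] * (1 - w) + self.r[:, i + 1] * w

    def drdt_at(self, t: float) -> np.ndarray:
        return self.drdt[:, self.step_index(t)]

    def alveolus_rate(self, cls: int, t: float) -> float:
        """Volume rate of a single alveolus of class ``cls`` (m^3/s)."""
        i = self.step_index(t)
        return float(self.rate_acinus[cls, i]
                     / (self.class_mult[cls] * self.class_counts[cls]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format schedule table (one row per class per node time)."""
        rows = []
        gen_of_class = {0: "16-18", 1: "19-21", 2: "22", 3: "23"}
        for c in range(4):
            for i in range(self.n_steps + 1):
                j = min(i, self.n_steps - 1)
                rows.append(dict(
                    time_s=self.t[i], unit=CLASS_NAMES[c],
                    generation=gen_of_class[c],
                    radius_mm=self.r[c, i] * 1e3,
                    drdt_mm_s=self.drdt[c, j] * 1e3,
                    stiffened=bool(self.stiffened[j]),
                    capped=bool(self.capped[c, j])))
        return pd.DataFrame(rows)


def build_schedule(tree: AcinarTree, waveform: BreathingWaveform,
                   rule: Optional[ComplianceRule] = None,
                   dt: float = 1e-3) -> WallMotionSchedule:
    """Integrate the per-class radius trajectories over one breathing cycle.

    The oral waveform is divided down to the acinus inlet
    (``Q / 2**inlet_generation``); class volume rates are the acinus inlet
    flow times the class fractions, adjusted step by step for stiffening
    and the expansion cap, with the deficit redistributed to the
    generation-23 sacs.  Exhalation mirrors the inhalation path.
    """
    cfg = tree.config
    if rule is None:
        rule = ComplianceRule()
    cap = rule.cap_factor
    if cap is None:
        cap = max_expansion_factor(cfg.frc_ml, cfg.tlc_ml)

    fr = tree.class_fractions()
    counts = tree.class_counts().astype(float)
    mult = tree.class_mult().astype(float)
    f_class = tree.class_f()
    r0 = tree.class_frc_radii()
    active = counts > 0
    rcls = rule.redistribution_class
    if not active[rcls]:
        # fixture trees without sacs redistribute to the most distal class
        rcls = int(np.max(np.nonzero(active)))

    n_in = max(1, round(waveform.inhale_s / dt))
    dt_in = waveform.inhale_s / n_in
    n_ex = max(1, round(waveform.exhale_s / dt))
    dt_ex = waveform.exhale_s / n_ex
    # a single uniform grid keeps the bookkeeping simple; mirror exactly
    # when the phases are symmetric
    q_ac_in = generation_flow(waveform.q_inlet_lpm * LPM_TO_M3S,
                              cfg.inlet_generation)

    r_in = np.zeros((4, n_in + 1))
    r_in[:, 0] = r0
    drdt_in = np.zeros((4, n_in))
    rate_in = np.zeros((4, n_in))
    stiff_in = np.zeros(n_in, dtype=bool)
    capped_in = np.zeros((4, n_in), dtype=bool)
    cum_ml = np.zeros(n_in + 1)
    r_cap = r0 * (1.0 + cap)
    k_vol = f_class * (4.0 / 3.0) * math.pi   # V = k r^3 per alveolus

    q_oral = waveform.q_inlet_lpm * LPM_TO_M3S
    for i in range(n_in):
        rates = q_ac_in * fr.copy()
        stiff = cum_ml[i] >= rule.stiffening_threshold_ml - 1e-12
        stiff_in[i] = stiff
        if stiff:
            for c in range(4):
                if c != rcls and active[c] and rates[c] > 0:
                    deficit = rates[c] * (1.0 - rule.stiffening_factor)
                    rates[c] -= deficit
                    rates[rcls] += deficit
        # expansion cap with redistribution to the terminal class
        total_alv = counts * mult
        for c in range(4):
            if not active[c] or c == rcls or rates[c] <= 0:
                continue
            head = k_vol[c] * (r_cap[c] ** 3 - r_in[c, i] ** 3) * total_alv[c]
            allowed = max(min(rates[c], head / dt_in), 0.0)
            excess = rates[c] - allowed
            if excess > 0:
                capped_in[c, i] = True
                rates[c] = allowed
                rates[rcls] += excess
        if active[rcls] and rates[rcls] > 0:
            head = (k_vol[rcls] * (r_cap[rcls] ** 3 - r_in[rcls, i] ** 3)
                    * total_alv[rcls])
            if rates[rcls] * dt_in > head * (1.0 + 1e-9):
                raise ConservationError(
                    "generation-23 sacs are fully distended but the inlet "
                    "flow still demands volume; the configured waveform is "
                    "not attainable under the compliance rules")
        for c in range(4):
            if not active[c]:
                continue
            dv_alv = rates[c] * dt_in / total_alv[c]
            r3 = r_in[c, i] ** 3 + dv_alv / k_vol[c] * 1.0
            r_in[c, i + 1] = np.cbrt(r3)
            drdt_in[c, i] = (r_in[c, i + 1] - r_in[c, i]) / dt_in
        rate_in[:, i] = rates
        cum_ml[i + 1] = cum_ml[i] + q_oral * dt_in / ML_TO_M3

    # exhalation: reverse path at a duration-scaled identical rate
    scale = waveform.inhale_s / waveform.exhale_s
    idx = np.linspace(waveform.inhale_s, 0.0, n_ex + 1)
    # map exhale node k to inhale time T_in * (1 - k/n_ex)
    r_ex = np.zeros((4, n_ex + 1))
    for k in range(n_ex + 1):
        t_src = idx[k]
        j = min(int(round(t_src / dt_in)), n_in)
        r_ex[:, k] = r_in[:, j]
    drdt_ex = (r_ex[:, 1:] - r_ex[:, :-1]) / dt_ex
    rate_ex = np.zeros((4, n_ex))
    for k in range(n_ex):
        j = min(int(round(idx[k + 1] / dt_in)), n_in - 1)
        rate_ex[:, k] = -rate_in[:, j] * scale
    stiff_ex = np.zeros(n_ex, dtype=bool)
    capped_ex = np.zeros((4, n_ex), dtype=bool)
    for k in range(n_ex):
        j = min(int(round(idx[k + 1] / dt_in)), n_in - 1)
        stiff_ex[k] = stiff_in[j]
        capped_ex[:, k] = capped_in[:, j]

    t = np.concatenate([np.arange(n_in + 1) * dt_in,
                        waveform.inhale_s + np.arange(1, n_ex + 1) * dt_ex])
    r = np.concatenate([r_in, r_ex[:, 1:]], axis=1)
    drdt = np.concatenate([drdt_in, drdt_ex], axis=1)
    rate = np.concatenate([rate_in, rate_ex], axis=1)
    q_ac = np.concatenate([np.full(n_in, q_ac_in),
                           np.full(n_ex, -q_ac_in * scale)])
    sched = WallMotionSchedule(
        tree=tree, waveform=waveform, rule=rule, dt=dt_in,
        t=t, r=r, drdt=drdt, rate_acinus=rate, q_acinus=q_ac,
        cumulative_ml=np.concatenate(
            [cum_ml, [cum_ml[min(int(round(idx[k] / dt_in)), n_in)]
                      for k in range(1, n_ex + 1)]]),
        stiffened=np.concatenate([stiff_in, stiff_ex]),
        capped=np.concatenate([capped_in, capped_ex], axis=1),
        n_inhale=n_in, class_counts=counts, class_mult=mult)
    return sched
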