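"""Run configuration: schema-validated settings for geometry, breathing,
particles and dosimetry.

Every default is either a published morphometric / physiological value
(alveolus dimensions, per-unit alveoli counts, FRC/TLC, breathing waveform,
injection rate) or a declared package design choice (duct table, placement
margins, air properties, numerical steps).  Units are stated in the field
name; geometry lengths are millimetres in config and converted to SI metres
when the tree is built.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: Weibel-type symmetric airway table for the acinar generations,
#: ``generation -> (length_mm, diameter_mm)``.  Package default for the duct
#: dimensions; rigid ducts, so no breathing-phase rescaling is applied.
WEIBEL_ACINAR_TABLE_MM: dict[int, tuple[float, float]] = {
    16: (1.65, 0.60),
    17: (1.41, 0.54),
    18: (1.17, 0.50),
    19: (0.99, 0.47),
    20: (0.83, 0.45),
    21: (0.70, 0.43),
    22: (0.59, 0.41),
    23: (0.50, 0.41),
}

#: Default number of discrete alveoli attached per generation in the resolved
#: units.  Per-unit totals (84 / 182 / 25 + 4 sacs) are fixed by the model;
#: the split across generations inside a unit is a configurable design choice.
DEFAULT_ALVEOLI_PER_GENERATION: dict[int, int] = {
    16: 12, 17: 24, 18: 48,      # TBU 16-18: 84 total
    19: 40, 20: 34, 21: 108,     # TBU 19-21: 182 total
    22: 25,                      # DBU duct generation
}

#: Alveolar volume fraction of the inhaled air taken up by each deformation
#: class (TBU 16-18, TBU 19-21, generation 22, generation 23).  They sum to 1.
DEFAULT_VOLUME_FRACTIONS: dict[str, float] = {
    "16_18": 0.03,
    "19_21": 0.25,
    "22": 0.27,
    "23": 0.45,
}


class GeometryConfig(BaseModel):
    """Parametric description of the acinar tree."""

    alveolus_radius_mm: float = 0.105      # AR, morphometric value
    neck_radius_mm: float = 0.085          # NR, morphometric value
    alveolus_depth_mm: float = 0.22        # D, mouth-to-floor depth incl. neck
    f_alveolus: float = 0.75               # partial-spheroid volume fraction
    f_sac: float = 0.97                    # terminal sacs are almost closed
    septal_gap_mm: float = 0.005           # minimum inter-alveolus surface gap
    sac_equivalent_alveoli: int = 17       # one sac stands for this many alveoli
    sacs_per_dbu: int = 4
    branch_half_angle_deg: float = 35.0
    inter_unit_rotation_deg: float = 90.0
    frc_ml: float = 3000.0
    tlc_ml: float = 6000.0
    acinus_count: int = 2 ** 15            # symmetric-lung acinus multiplicity
    inlet_generation: int = 16
    duct_table_mm: dict[int, tuple[float, float]] = Field(
        default_factory=lambda: dict(WEIBEL_ACINAR_TABLE_MM))
    duct_scale: float = 1.0                # optional isotropic duct rescale
    alveoli_per_generation: dict[int, int] = Field(
        default_factory=lambda: dict(DEFAULT_ALVEOLI_PER_GENERATION))
    alveolar_volume_fractions: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_VOLUME_FRACTIONS))
    # placement margins (axial dead zones near duct ends, mm)
    inlet_margin_mm: float = 0.03          # proximal margin on unit-inlet ducts
    child_margin_mm: float = 0.10          # proximal margin below a bifurcation
    distal_margin_mm: float = 0.03         # distal margin on terminal ducts
    parent_distal_margin_mm: float = 0.19  # distal margin above a bifurcation
    placement_max_attempts: int = 80
    seed: int = 0

    @field_validator("alveolus_radius_mm", "neck_radius_mm", "frc_ml", "tlc_ml")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        if not (0 < self.f_alveolus <= 1 and 0 < self.f_sac <= 1):
            raise ValueError("fractional volumes must lie in (0, 1]")
        total = sum(self.alveolar_volume_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"alveolar volume fractions must sum to 1, got {total!r}")
        if self.tlc_ml <= self.frc_ml:
            raise ValueError("TLC must exceed FRC")
        return self

    @property
    def max_expansion_factor(self) -> float:
        """Largest allowed fractional radius increase, (TLC/FRC)^(1/3) - 1."""
        return (self.tlc_ml / self.frc_ml) ** (1.0 / 3.0) - 1.0


class BreathingConfig(BaseModel):
    """Breathing waveform and tissue-compliance rules.

    The flow rate and tidal volume are oral-scale quantities; the schedule
    builder divides them down to the generation-16 acinus inlet.
    """

    flow_lpm: float = 15.0
    inhale_s: float = 2.0
    exhale_s: Optional[float] = None       # None -> symmetric with inhalation
    tidal_ml: Optional[float] = None       # None -> flow x inhale duration
    dt_s: float = 1e-3                     # schedule time step
    stiffening_threshold_ml: float = 500.0
    stiffening_factor: float = 0.5
    cap_factor: Optional[float] = None     # None -> (TLC/FRC)^(1/3) - 1

    @model_validator(mode="after")
    def _check(self) -> "BreathingConfig":
        if self.flow_lpm < 0 or self.inhale_s <= 0 or self.dt_s <= 0:
            raise ValueError("flow must be >= 0 and durations positive")
        if self.tidal_ml is not None:
            implied = self.flow_lpm * 1000.0 / 60.0 * self.inhale_s
            if self.flow_lpm > 0 and abs(self.tidal_ml - implied) > 1e-9 * max(implied, 1.0):
                raise ValueError(
                    f"tidal volume {self.tidal_ml} ml inconsistent with "
                    f"flow x inhale duration = {implied} ml")
        if not (0 < self.stiffening_factor <= 1):
            raise ValueError("stiffening factor must lie in (0, 1]")
        return self


class ParticlesConfig(BaseModel):
    """Lagrangian tracker settings."""

    diameters_um: list[float] = Field(default_factory=lambda: [2.0, 3.0, 5.0, 7.0, 10.0])
    density_kg_m3: float = 1000.0          # unit-density aerosol convention
    injection_rate_per_s: float = 20000.0
    n_per_size: Optional[int] = None       # override count; None -> rate x inhale
    dt_s: float = 0.5e-3
    air_viscosity_pa_s: float = 1.81e-5
    air_density_kg_m3: float = 1.2
    gravity_m_s2: float = 9.81             # acts along global -z
    vortex_strength: float = 0.3           # cavity recirculation constant
    bolus: bool = False                    # inject all particles at t = 0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ParticlesConfig":
        if any(d <= 0 for d in self.diameters_um):
            raise ValueError("particle diameters must be positive")
        if self.dt_s <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("dt and density must be positive")
        return self


class DosimetryRow(BaseModel):
    d_um: float
    phi: float = Field(ge=0.0, le=1.0)
    eta_E: float = Field(ge=0.0, le=1.0)
    eta_F: float = Field(ge=0.0, le=1.0)


class DosimetryConfig(BaseModel):
    """Upper-airway filtering table used for the whole-lung translation.

    The extra-thoracic / tracheobronchial efficiencies and the alveolar
    air-volume fraction are user-supplied (synthetic defaults here); they are
    inputs to the translation, not outputs of the acinar model.
    """

    table: list[DosimetryRow] = Field(default_factory=lambda: [
        DosimetryRow(d_um=2.0, phi=0.9, eta_E=0.05, eta_F=0.05),
        DosimetryRow(d_um=3.0, phi=0.85, eta_E=0.10, eta_F=0.08),
        DosimetryRow(d_um=5.0, phi=0.8, eta_E=0.25, eta_F=0.15),
        DosimetryRow(d_um=7.0, phi=0.7, eta_E=0.45, eta_F=0.25),
        DosimetryRow(d_um=10.0, phi=0.6, eta_E=0.70, eta_F=0.35),
    ])


class RunConfig(BaseModel):
    """Top-level configuration for a full simulation run."""

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    breathing: BreathingConfig = Field(default_factory=BreathingConfig)
    particles: ParticlesConfig = Field(default_factory=ParticlesConfig)
    dosimetry: DosimetryConfig = Field(default_factory=DosimetryConfig)
    seed: int = 0
    output_dir: str = "results"
    verbosity: int = 1


def load_config(path: str) -> RunConfig:
    """Read a YAML run configuration; raises on unknown or missing keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
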