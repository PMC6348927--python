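# Methods

This note records the model assumptions, the numerical choices and the
design decisions behind `acinosim`, and what its passing tests do and do
not demonstrate about real acinar aerosol transport.

## Geometry

The acinus is represented by three resolved units in a symmetric
dichotomous tree — TBU 16–18 (multiplicity 1), TBU 19–21 (multiplicity 8)
and DBU 22–23 (multiplicity 64) — each a cascade of planar symmetric
bifurcations with a configurable half-angle (default 35°). Only one copy
of each unit is resolved; the others are represented by multiplicity
factors and by the handoff protocol at the unit boundary planes.
Consecutive units are rotated 90° (configurable) about the connecting
axis, and every unit stores its rotation relative to the laboratory frame
so that gravity (−z) is applied consistently.

Duct dimensions default to the Weibel symmetric-lung table as printed
(generation 16: 1.65 mm × 0.60 mm, …, generation 23: 0.50 mm × 0.41 mm).
The ducts are treated as rigid, following the observation that at resting
breathing the alveoli account for nearly all of the volume change, so no
breathing-phase rescaling is applied to them; an optional isotropic scale
factor is exposed in the configuration. We deliberately do **not** shrink
the table to FRC: a packing analysis (below) shows the required alveolar
density does not fit on FRC-scaled sleeves with any positive septal gap.

**Alveolus parametrisation.** Each alveolus is a partial spheroid
retaining the volume fraction f = 0.75 (terminal sacs f = 0.97) of a
sphere of radius AR = 0.105 mm, anchored through a cylindrical neck of
radius NR = 0.085 mm; the mouth-to-floor depth is D = 0.22 mm (the upper
end of the morphometric 0.20–0.22 mm range, which maximises the
clearance between neighbouring cavities). The cut plane of an f-spheroid
sits at κ_a·r from the centre, where κ_a solves
c²(3−c) = 4(1−f), c = 1−κ_a (κ_a ≈ 0.347 for f = 0.75). The closed-form
volume f·(4/3)πr³ is verified against Monte-Carlo integration of the
cap-truncated solid in the tests.

**Placement.** Alveoli are laid out on ring lattices around each duct:
rings of evenly spaced mouths at the near-close-packed chord spacing
2·AR + gap (gap = 5 µm septal clearance, a physiological septum
thickness), hexagonally offset between rings, with one random azimuthal
phase per duct. Because sibling duct sleeves interpenetrate near
bifurcations, a generation's alveoli are placed jointly across its ducts
by a greedy pass (tightest generation first, random site order) that
drops conflicting crotch sites, with whole-unit retries under fresh
phases and a hard `GeometryError` if the density is infeasible. Uniform
rejection sampling was rejected as the placement algorithm: random
sequential adsorption jams at ~55% surface coverage while 182 alveoli on
the TBU 19–21 sleeves require ~85%, so no rejection-sampled configuration
can reach the published per-unit counts. The per-generation split within
a unit is not morphometrically fixed; the defaults (12/24/48, 40/34/108,
25, 4 sacs) were chosen inside the measured joint packing capacity
(saturation ≈ 44/38/112 for generations 19–21) and are configuration
parameters. A global pairwise check verifies the septal gap for every
constructed tree.

**Terminal sacs.** Each generation-23 duct ends in two quasi-spherical
sacs placed out of the bifurcation plane; each sac conserves the volume
of one generation-23 duct plus 17 discrete alveoli (radius ≈ 0.316 mm at
FRC, f = 0.97), consistent with the observation that terminal alveoli
cluster into larger, less demarcated spaces.

## Ventilation

The oral waveform (default: constant 15 L/min for 2 s, i.e. 500 ml tidal
volume) is divided to the generation-16 inlet by the symmetric-dichotomy
rule Q_g = Q/2^g and partitioned among four deformation classes —
TBU 16–18, TBU 19–21, generation-22 alveoli, generation-23 sacs — in
proportion to their alveolar volume fractions 0.03/0.25/0.27/0.45 (whole
acinus; divided by multiplicity for one resolved copy). Per-alveolus
rates follow by dividing by the class counts, and radii update by the
exact cubic root each step (1 ms default), so no ODE integration error
enters the kinematics.

Compliance rules: once the cumulative inhaled volume passes 500 ml the
non-terminal class rates are multiplied by 0.5 (strain stiffening); any
class reaching the expansion cap (1+cap)·r₀ with cap = (TLC/FRC)^⅓ − 1
(0.26 for 3000/6000 ml) stops expanding; in both cases the displaced flow
moves to the generation-23 sacs, and a `ConservationError` is raised if
the sacs themselves cannot absorb it (the redistribution is never
silently dropped). At 500 ml tidal volume neither rule engages (peak
radius ratio 1.205); at 1000 ml stiffening starts exactly at t = 2 s and
the proximal class caps at 1.26 — the sacs absorb the difference with the
global balance Σ rates = Q_acinus preserved to machine precision.

Exhalation retraces the inhalation radius path in reverse at a
duration-scaled rate (identical rate for the symmetric default), so the
cycle closes exactly on the FRC radii and the schedule is time-reversal
symmetric; whether stiffening "applies" during exhalation is therefore
moot — the mirrored path inherits it. Geometric hysteresis is not
modelled.

## Airflow

The flow field is a reduced-order stand-in for a moving-mesh
Navier–Stokes solve; its contract is mass consistency, wall-velocity
matching and the recirculating-to-radial regime trend — not pointwise
agreement with CFD streamlines.

*Ducts.* Quasi-steady Poiseuille profiles (Reynolds number ≲ 0.5 at the
inlet) whose flow rate decreases along the duct as alveolar uptake is
withdrawn at each mouth station. Junction splits are weighted by the
downstream demand (the subtree's wall-motion uptake), which reduces to
the symmetric 50/50 split for equal alveoli counts and closes the
generation-wise audit — flow in = flow to children + mouth fluxes — to
machine precision even though the placed alveoli counts differ slightly
between sibling ducts.

*Alveolar cavities.* The cavity velocity is

    u = (ṙ/r)·ρ⃗  +  J(t)·(1 − (ρ/r)²)·ê  +  vortex,

a self-similar dilation matching the wall-normal speed ṙ exactly
(jet and vortex are tangential at the wall), plus an axial mouth jet
along the neck axis ê whose strength J matches the neck plug velocity
dV/dt / (π·NR²) at the mouth plane. The plug carries exactly the
alveolar volume rate through the physical mouth (the neck opening), which
is where the mouth-flux quadrature contract is enforced. A purely
radial source/sink construction was rejected: any spherically symmetric
field with u(wall) = ṙ > 0 and net mouth influx must contain an interior
stagnation sphere, which is attracting during exhalation and traps
tracer particles, destroying the time-reversibility of the advection;
the dilation + jet field is free of attracting interior structures. The
vortex is a solid-body-core recirculation with circulation proportional
to the local duct mean velocity (constant 0.3, uncalibrated — no printed
quantity anchors it); it reproduces the qualitative proximal
recirculation and vanishes with the duct shear.

*Flow regime.* The ratio |dV/dt| / (ū_duct · mouth area) quantifies the
radial-to-shear balance per alveolus. It rises monotonically across the
four deformation classes (0.008 → 0.025 → 0.10 → 0.84 at mid-inhalation,
15 L/min) and from generation 17 to 21, matching the recirculating →
radial transition. It is *not* strictly monotone per generation: the
stated volume fractions give TBU 16–18 alveoli about twice the
per-alveolus flux of TBU 19–21 (0.03·Q/84 vs 0.25·Q/(8·182)) while the
duct velocity falls only ~1.8× across that boundary, so the ratio dips
slightly from generation 18 to 19. This is arithmetic inherent in the
model constants, not an implementation artefact.

## Particle transport

Spheres of 2–10 µm (unit density 1000 kg/m³ — the aerosol convention;
the source model does not state a density) move under Schiller–Naumann
drag and gravity. The velocity ODE is linear in v and integrated
analytically per step (exact for constant u), stiff-safe for relaxation
times τ = ρ_p d²/18µ of 1.2×10⁻⁸–3×10⁻⁴ s against the 0.5 ms step;
positions update trapezoidally. Air properties default to
µ = 1.81×10⁻⁵ Pa·s, ρ = 1.2 kg/m³. Brownian diffusion is omitted
(relevant below ~0.5 µm).

Injection is spatially uniform over the generation-16 inlet disc for the
whole inhalation (20 000 particles/s by default; tests and the
acceptance script use 2000 per size to fit desk-scale runtimes) with the
local air velocity as the initial velocity. Deposition is on contact:
the particle centre within one radius of the union-of-primitives surface
(ducts as open-ended cylinders, cavities as spheres, necks as capsules
extended one neck radius into the lumen so the mouth jet joins the duct
flow). Because a 0.5 ms step can cross the ~10 µm septal clearance
between a duct wall and a cavity, a cavity may only be *entered* through
its neck capsule; a direct duct→cavity or outside→cavity jump is scored
as a wall contact. This concentrates deposits at alveolar entrance rings
and bifurcation ridges — the hotspots reported for acinar geometries —
but it also means the absolute deposition fractions run higher than a
body-fitted CFD geometry would give (sharp-cornered junctions expose
septal outer walls to the stream). Deposition *trends* — not absolute
values — are therefore the validated surface.

Handoffs: downstream, a particle crossing an outlet plane is re-seeded
at the resolved child unit's inlet preserving its normalised radial
coordinate, azimuth and velocity components (preserving the near-wall
enrichment that drives alveolar entry); upstream during exhalation it is
placed at a uniformly random outlet of the parent unit, and particles
crossing the generation-16 inlet leave the domain. The random outlet
choice is the model's convective-mixing mechanism: it intentionally
breaks deterministic reversibility for unit-crossing particles. The
time-reversibility of the advection itself is verified on tracers
(gravity off, vortex off) that never cross a unit boundary: 100% return
to their injection radial position within 0.05 of the radius fraction.

## Dosimetry

DF = φ(1−η_E)(1−η_F)η_A translates the model's alveolar efficiency η_A
into a whole-lung alveolar deposition fraction. The upper-airway tables
(φ, η_E, η_F per size) are measurement inputs; the bundled defaults are
synthetic placeholders for exercising the pipeline, so no quantitative
in vivo comparison is implied by the package outputs.

## Problem sizes and determinism

Default study conditions: 15 L/min, tidal volumes 500 ml (2 s + 2 s) and
1000 ml (4 s + 4 s); schedule step 1 ms; tracker step 0.5 ms; particle
sizes {2, 3, 5, 7, 10} µm at 2000 particles per size in the test and
acceptance runs. All randomness (placement phases, injection positions,
exhalation re-injection) flows from a single seeded generator; identical
configuration and seed reproduce byte-identical outputs.

## Known limitations

- Isotropic balloon-like alveolar deformation only; no anisotropic or
  accordion modes, no recruitment/derecruitment, no hysteresis.
- The reduced-order flow has velocity discontinuities at containment
  boundaries (duct/neck/cavity); particles crossing slow regions can
  linger near mouths ("beaching"), a behaviour a resolved shear layer
  would soften.
- Inflated alveoli (radius ×1.26) of neighbouring lattice sites may
  interpenetrate geometrically; the septal gap is guaranteed at FRC.
- Junction wedges between straight cylindrical ducts expose outer
  alveolar walls to the stream, inflating impaction-like deposition
  relative to smooth body-fitted geometries; absolute DF values are
  accordingly high while size/tidal-volume/regional trends are robust.
- One resolved copy per unit means intra-generation heterogeneity
  (gravity orientation of parallel units, lobar differences) is not
  represented.
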