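"""Whole-lung translation of acinar deposition efficiencies.

The acinar model predicts the alveolar-region deposition efficiency
``eta_A`` (the fraction of particles entering the generation-16 inlet that
deposit).  To compare with in vivo whole-lung measurements this is
filtered through the upper airways:

    DF_alveolar = phi * (1 - eta_E) * (1 - eta_F) * eta_A

where ``phi`` is the volume fraction of inhaled air that comes to rest in
the alveolar region, and ``eta_E`` / ``eta_F`` are the extra-thoracic and
tracheobronchial deposition efficiencies.  Those upper-airway tables are
measurement inputs supplied through the configuration, not outputs of
this model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DosimetryConfig
from .particles import PHASE_EXHALE, PHASE_INHALE, DepositionRecord


def whole_lung_df(eta_A: float, phi: float, eta_E: float, eta_F: float) -> float:
    """Alveolar-region whole-lung deposition fraction,
    ``phi (1 - eta_E) (1 - eta_F) eta_A``."""
    for name, v in (("eta_A", eta_A), ("phi", phi),
                    ("eta_E", eta_E), ("eta_F", eta_F)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return phi * (1.0 - eta_E) * (1.0 - eta_F) * eta_A


def summary_table(record: DepositionRecord,
                  config: DosimetryConfig) -> pd.DataFrame:
    """Per-size summary: model alveolar efficiency, whole-lung DF and
    regional/phase splits."""
    rows = []
    table = {row.d_um: row for row in config.table}
    for d in np.asarray(record.diameters_um, dtype=float):
        eta_a = record.deposition_fraction(d_um=d)
        row = dict(d_um=d, eta_A=eta_a)
        if d in table:
            p = table[d]
            row.update(phi=p.phi, eta_E=p.eta_E, eta_F=p.eta_F,
                       DF_alveolar=whole_lung_df(eta_a, p.phi, p.eta_E, p.eta_F))
        else:
            row.update(phi=np.nan, eta_E=np.nan, eta_F=np.nan,
                       DF_alveolar=np.nan)
        for region in ("proximal", "mid", "distal"):
            row[f"DF_{region}"] = record.deposition_fraction(d_um=d, region=region)
        row["DF_inhale"] = record.deposition_fraction(d_um=d, phase=PHASE_INHALE)
        row["DF_exhale"] = record.deposition_fraction(d_um=d, phase=PHASE_EXHALE)
        row["suspended_fraction"] = record.suspended_fraction(d_um=d)
        rows.append(row)
    return pd.DataFrame(rows)
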