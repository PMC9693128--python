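"""Published reference records from a set of Wurster film-coating
experiments, transcribed as in-memory tables.

Three tables are bundled:

- ``coating_runs()`` — the per-run process ledger: pellet load, partition
  gap, inlet air humidity, LOD before/after coating, process yield and
  consumed suspension, with the endpoint mode (in-line thickness target for
  P-runs, fixed suspension mass for C-runs).
- ``core_batches()`` — geometry of the drug-layered starting pellets per
  API batch: median CED, SSA_m, SSA_V, granular density and pellets per mg.
- ``sr_coated()`` — SSA_m of the SR-coated pellets, film thickness after
  drying, and the film density estimated from the shell mass balance.

These printed values are inputs for validation; the simulator can generate
arbitrarily parameterised runs with the same structure.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["coating_runs", "core_batches", "sr_coated", "OMEGA"]

#: dry-matter mass fraction of the coating suspension
OMEGA = 0.207

_COATING_RUNS = """\
exp,pellet_batch,load_g,gap_mm,inlet_gkg,lod_start_pct,lod_finish_pct,yield_pct,susp_g,endpoint_mode
P1,1a,1000,20,1.3,0.72,0.60,62.6,453.0,thickness
P2,1b,1000,20,1.0,0.70,0.60,,,thickness
P3,1c,1000,20,0.6,0.72,0.60,67.9,459.0,thickness
P4,2,1000,20,0.4,1.74,0.72,71.3,442.0,thickness
P5,2,1000,20,0.2,1.78,0.66,71.3,453.3,thickness
P-G,2,1000,10,0.2,1.80,0.70,66.4,457.0,thickness
P-Q,2,600,10,0.2,1.82,0.54,62.2,279.0,thickness
P-H,2,1000,20,5.8,1.78,0.66,74.8,513.2,thickness
C1,2,1000,20,0.2,1.76,0.68,73.1,463.0,mass
C2,2,1000,20,0.3,1.80,0.68,70.9,463.0,mass
C3,2,1000,20,0.3,1.80,0.74,69.7,463.0,mass
C-G,2,1000,10,0.2,1.79,0.68,71.6,463.0,mass
C-Q,2,600,10,0.5,1.82,0.56,70.8,277.0,mass
C-H,2,1000,20,5.4,1.78,0.64,74.7,463.0,mass
"""

_CORE_BATCHES = """\
batch,median_ced_um,ssa_m_um2_mg,ssa_v_per_um,density_g_cm3,n_per_mass_mg
1a,1070.1,4.47e6,5.71e-3,1.278,1.288
1b,1078.6,4.52e6,5.65e-3,1.251,1.282
1c,1067.3,4.49e6,5.72e-3,1.275,1.299
2,1094.2,4.56e6,5.58e-3,1.224,1.256
"""

_SR_COATED = """\
exp,ssa_m_um2_mg,h_after_drying_um,coating_density_g_cm3
P4,4.065e6,8.0,1.76
P5,4.054e6,8.1,1.78
P-G,3.969e6,7.9,1.72
P-Q,4.024e6,5.8,2.24
P-H,4.423e6,7.7,2.23
"""


def _read(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text))


def coating_runs() -> pd.DataFrame:
    """Process ledger of the 14 coating runs (P2's yield and suspension were
    lost to a weighing-system failure and are NaN)."""
    return _read(_COATING_RUNS)


def core_batches() -> pd.DataFrame:
    """Geometry of the drug-layered starting pellet batches."""
    return _read(_CORE_BATCHES)


def sr_coated() -> pd.DataFrame:
    """SR-coated pellet surface, film thickness after drying and estimated
    film density for the in-line-monitored runs."""
    return _read(_SR_COATED)
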