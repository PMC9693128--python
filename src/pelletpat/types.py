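"""Domain containers shared across the pipeline.

Units follow instrument conventions throughout: diameters and coating
thickness in micrometres, masses in grams unless a field name says mg,
densities in g/cm^3, times in minutes for process monitoring and hours
for dissolution, LOD (loss on drying) in percent mass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CoatingRunConfig",
    "SizeFrame",
    "LODTrajectory",
    "ProcessRecord",
    "DissolutionProfile",
    "ReleaseModelParams",
    "PelletBatch",
    "BatchMetrics",
    "YieldInput",
    "CoatingDensityInput",
    "ThicknessPoint",
    "ReferenceSelection",
    "ImageScale",
    "ParticleMeasurement",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CoatingRunConfig:
    """Parameterisation of one simulated Wurster coating run.

    Defaults describe a 1000 g batch of drug-layered pellets (median
    diameter ~1094 um) coated with an aqueous polymer suspension of
    20.7 % dry matter at 14 g/min, stopped at a 9.4 um film.
    """

    load_mass: float = 1000.0          # g of starting drug-layered pellets
    spray_rate: float = 14.0           # g suspension / min
    dry_fraction: float = 0.207        # mass fraction of solids (omega)
    process_yield: float = 0.713       # deposition efficiency (gamma)
    core_median_diameter: float = 1094.2   # um
    core_diameter_cv: float = 0.025        # sd/median of core diameters
    core_granular_density: float = 1.224   # g/cm^3
    n_per_mass: float = 1.256              # pellets per mg (N_m)
    ssa_m_core: float = 4.56e6             # um^2/mg, core specific surface
    coating_density: float = 1.76          # g/cm^3 of the deposited film
    target_thickness: float = 9.4          # um, endpoint threshold
    frame_interval: float = 1.0            # min between size frames
    frame_particle_count_range: tuple[int, int] = (25000, 50000)
    dip_depth: float = 6.0                 # um initial D50 shrink (diameter)
    dip_duration: float = 6.0              # min of warm-up shrink phase
    inlet_humidity: float = 0.4            # g water / kg dry air
    lod_start: float = 1.74                # % mass
    lod_equilibrium: float = 0.70          # % mass
    lod_rate: float = 0.08                 # 1/min first-order relaxation
    endpoint_mode: str = "thickness"       # thickness|true_thickness|mass
    suspension_mass: Optional[float] = None  # g, required for mode "mass"
    reference_window: float = 10.0         # min, D50 reference search window
    max_duration: float = 240.0            # min before declaring no endpoint
    drying_shrink: float = 1.0             # multiplicative thickness factor at drying
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "load_mass": self.load_mass,
            "core_median_diameter": self.core_median_diameter,
            "core_granular_density": self.core_granular_density,
            "n_per_mass": self.n_per_mass,
            "ssa_m_core": self.ssa_m_core,
            "coating_density": self.coating_density,
            "target_thickness": self.target_thickness,
            "frame_interval": self.frame_interval,
            "max_duration": self.max_duration,
        }
        for name, val in positive.items():
            _require(val > 0, f"{name} must be strictly positive, got {val}")
        _require(self.spray_rate >= 0, "spray_rate must be non-negative")
        _require(0 < self.process_yield <= 1, "process_yield must be in (0, 1]")
        _require(0 < self.dry_fraction < 1, "dry_fraction must be in (0, 1)")
        _require(self.core_diameter_cv >= 0, "core_diameter_cv must be >= 0")
        _require(self.dip_duration >= 0, "dip_duration must be >= 0")
        _require(self.dip_depth >= 0, "dip_depth must be >= 0")
        lo, hi = self.frame_particle_count_range
        _require(1 <= lo <= hi, "frame_particle_count_range must be 1 <= lo <= hi")
        _require(0 <= self.lod_start < 100, "lod_start must be a percentage in [0,100)")
        _require(0 <= self.lod_equilibrium < 100, "lod_equilibrium must be in [0,100)")
        _require(self.lod_rate >= 0, "lod_rate must be >= 0")
        _require(
            self.endpoint_mode in ("thickness", "true_thickness", "mass"),
            f"unknown endpoint_mode {self.endpoint_mode!r}",
        )
        if self.endpoint_mode == "mass":
            _require(
                self.suspension_mass is not None and self.suspension_mass > 0,
                "endpoint_mode='mass' requires a positive suspension_mass",
            )
        _require(0 < self.drying_shrink <= 1, "drying_shrink must be in (0, 1]")

    def replace(self, **changes) -> "CoatingRunConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SizeFrame:
    """One minute of in-line sizing: median diameter of the moving pellet
    population with the standard error of the mean as uncertainty proxy."""

    time: float   # min
    d50: float    # um
    se: float     # um, SE of the mean diameter
    n: int        # particles in the frame

    def __post_init__(self) -> None:
        _require(self.d50 > 0, "d50 must be positive")
        _require(self.se >= 0, "se must be non-negative")
        _require(self.n >= 1, "n must be >= 1")


@dataclass(frozen=True)
class LODTrajectory:
    times: np.ndarray   # min
    values: np.ndarray  # % mass

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        _require(t.shape == v.shape, "times and values must have equal length")
        _require(bool(np.all((v >= 0) & (v < 100))), "LOD must be in [0, 100)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ProcessRecord:
    """One coating run's ledger, mirroring the process-record table."""

    exp: str
    load_g: float
    inlet_gkg: float
    lod_start_pct: float
    lod_finish_pct: float
    yield_fraction: float
    suspension_g: float           # consumed suspension at stop
    endpoint_mode: str
    endpoint_time_min: Optional[float]   # None => endpoint never reached
    final_thickness_um: float            # deposited (dry-equivalent) thickness

    @property
    def reached_endpoint(self) -> bool:
        return self.endpoint_time_min is not None

    @property
    def delta_lod(self) -> float:
        return self.lod_start_pct - self.lod_finish_pct


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative %-released curve for one run."""

    run: str
    times: np.ndarray     # h
    released: np.ndarray  # % of dose

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.released, dtype=float)
        _require(t.shape == r.shape, "times and released must have equal length")
        _require(bool(np.all(np.diff(t) > 0)), "times must be strictly increasing")
        _require(bool(np.all((r >= 0) & (r <= 100))), "released must be in [0, 100]")
        _require(bool(np.all(np.diff(r) >= -1e-9)), "released must be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "released", r)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ReleaseModelParams:
    """Reservoir-membrane release model dm/dt = S/h * K * dc with the
    permeability K tied inversely to coating density: K = permeability_scale / rho."""

    surface: float             # um^2 total film surface per sample
    thickness: float           # um
    permeability_scale: float  # um^2 * (g/cm^3) / s
    gradient: float            # mg / um^3 across the film (sink phase)
    dose: float                # mg drug in the sample
    coating_density: float = 1.76  # g/cm^3
    sink_fraction: float = 0.9     # released fraction at which solid drug is exhausted

    def __post_init__(self) -> None:
        for name in ("surface", "permeability_scale", "gradient", "dose",
                     "coating_density"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.thickness > 0, "thickness must be positive (h=0 undefined)")
        _require(0 < self.sink_fraction <= 1, "sink_fraction must be in (0, 1]")

    @property
    def permeability(self) -> float:
        """K in um^2/s."""
        return self.permeability_scale / self.coating_density


@dataclass(frozen=True)
class PelletBatch:
    """Per-pellet caliper measurements plus the weighed sample mass."""

    max_feret: np.ndarray   # um
    perp_feret: np.ndarray  # um
    sample_mass: float      # mg

    def __post_init__(self) -> None:
        a = np.asarray(self.max_feret, dtype=float)
        b = np.asarray(self.perp_feret, dtype=float)
        _require(a.shape == b.shape, "max_feret and perp_feret must have equal length")
        if a.size:
            _require(bool(np.all(b > 0)), "diameters must be positive")
            _require(bool(np.all(a >= b - 1e-9)), "max_feret must be >= perp_feret")
            _require(self.sample_mass > 0, "sample_mass must be positive for a non-empty batch")
        else:
            _require(self.sample_mass >= 0, "sample_mass must be non-negative")
        object.__setattr__(self, "max_feret", a)
        object.__setattr__(self, "perp_feret", b)

    @property
    def n(self) -> int:
        return int(self.max_feret.size)

    @property
    def ced(self) -> np.ndarray:
        """Projected-area circle-equivalent diameter of the a*b ellipse."""
        return np.sqrt(self.max_feret * self.perp_feret)


@dataclass(frozen=True)
class BatchMetrics:
    median_ced: float        # um
    ssa_v: float             # 1/um
    ssa_m: float             # um^2/mg
    granular_density: float  # g/cm^3
    n_per_mass: float        # 1/mg


@dataclass(frozen=True)
class YieldInput:
    """Mass-balance inputs for the process-yield formula; LOD in percent."""

    m_s: float           # g pellets charged
    m_f: float           # g pellets recovered
    lod_s: float         # % mass, before coating
    lod_f: float         # % mass, after coating
    m_susp: float        # g suspension sprayed
    dry_fraction: float = 0.207

    def __post_init__(self) -> None:
        _require(self.m_s > 0 and self.m_f > 0, "pellet masses must be positive")
        _require(self.m_susp > 0, "m_susp must be positive")
        for lod in (self.lod_s, self.lod_f):
            _require(0 <= lod < 100, "LOD must be a percentage in [0, 100)")
        _require(0 < self.dry_fraction < 1, "dry_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CoatingDensityInput:
    m_susp_sprayed: float   # g
    process_yield: float    # fraction
    dry_fraction: float     # omega
    n_per_mass: float       # 1/mg (core batch)
    ssa_m_core: float       # um^2/mg (core batch)
    m_cores: float          # g
    thickness: float        # um, film thickness after drying

    def __post_init__(self) -> None:
        for name in ("m_susp_sprayed", "process_yield", "dry_fraction",
                     "n_per_mass", "ssa_m_core", "m_cores"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.process_yield <= 1, "process_yield must be <= 1")
        _require(self.thickness > 0, "thickness must be positive")


@dataclass(frozen=True)
class ThicknessPoint:
    time: float       # min
    thickness: float  # um; may be negative during the initial dip
    se: float         # um

    def __post_init__(self) -> None:
        _require(self.se >= 0, "se must be non-negative")


@dataclass(frozen=True)
class ReferenceSelection:
    time: float     # min
    d50: float      # um
    se: float       # um at the reference frame
    window: float   # min searched

    def __post_init__(self) -> None:
        _require(self.time <= self.window, "reference time must lie inside the window")


@dataclass(frozen=True)
class ImageScale:
    microns_per_pixel: float

    def __post_init__(self) -> None:
        _require(self.microns_per_pixel > 0, "microns_per_pixel must be positive")

    @classmethod
    def from_dpi(cls, dpi: float) -> "ImageScale":
        return cls(25400.0 / dpi)


@dataclass(frozen=True)
class ParticleMeasurement:
    max_feret: float        # um
    perp_feret: float       # um
    ced: float              # um (area-equivalent)
    projected_area: float   # um^2
    centroid: tuple[float, float]  # um (row, col)

    def __post_init__(self) -> None:
        _require(self.perp_feret > 0, "perp_feret must be positive")
        _require(self.max_feret >= self.perp_feret - 1e-9,
                 "max_feret must be >= perp_feret")
        _require(self.ced > 0, "ced must be positive")
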