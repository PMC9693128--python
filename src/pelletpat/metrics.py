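"""Pellet geometry and mass-balance metrics.

Everything here is closed-form: specific surface per volume and per mass,
granular density, pellets per unit mass, coating process yield from the
LOD-corrected mass balance, film-coating density from the spherical-shell
geometry of the deposited film, and the release-rate screening factor
SSA_m / (rho * h).

Unit bookkeeping is exact: pellet masses enter in grams and are converted
to milligrams; lengths are micrometres; densities are returned in g/cm^3
(1 g/cm^3 == 1e-9 mg/um^3).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .synthkit import monodisperse_radius, shell_volume
from .types import BatchMetrics, CoatingDensityInput, PelletBatch, YieldInput

__all__ = [
    "batch_metrics",
    "granular_density_from_ssa",
    "process_yield",
    "coating_density",
    "release_factor",
    "YieldWarning",
]

_MG_PER_G = 1000.0
_G_CM3_PER_MG_UM3 = 1e9


class YieldWarning(UserWarning):
    """Process yield above 1: the mass balance is inconsistent."""


def batch_metrics(batch: PelletBatch) -> BatchMetrics:
    """Geometry metrics of a weighed pellet sample under the spheroid model.

    Each pellet is a prolate spheroid with the max Feret a as polar axis and
    the perpendicular Feret b as equatorial diameter: volume (pi/6) a b^2,
    surface taken as that of the volume-equivalent sphere pi d_eq^2 with
    d_eq = (a b^2)^(1/3). Then

        SSA_V = sum(S_i) / sum(V_i)            [1/um]
        rho   = m / (N * mean V)               [g/cm^3]
        SSA_m = SSA_V / rho                    [um^2/mg]  (exact identity)
        N_m   = N / m                          [1/mg]
    """
    if batch.n < 1:
        raise ValueError("batch_metrics requires at least one pellet")
    if batch.sample_mass <= 0:
        raise ValueError("batch_metrics requires a positive sample mass")
    a = batch.max_feret
    b = batch.perp_feret
    volumes = (math.pi / 6.0) * a * b**2            # um^3
    d_eq = np.cbrt(a * b**2)
    surfaces = math.pi * d_eq**2                    # um^2
    ssa_v = float(surfaces.sum() / volumes.sum())
    rho = batch.sample_mass / (batch.n * float(volumes.mean()))  # mg/um^3
    rho *= _G_CM3_PER_MG_UM3
    return BatchMetrics(
        median_ced=float(np.median(batch.ced)),
        ssa_v=ssa_v,
        ssa_m=ssa_v / rho * _G_CM3_PER_MG_UM3,
        granular_density=rho,
        n_per_mass=batch.n / batch.sample_mass,
    )


def granular_density_from_ssa(ssa_v: float, ssa_m: float) -> float:
    """Granular density [g/cm^3] as the ratio SSA_V [1/um] / SSA_m [um^2/mg]."""
    if ssa_v <= 0 or ssa_m <= 0:
        raise ValueError("specific surfaces must be positive")
    return ssa_v / ssa_m * _G_CM3_PER_MG_UM3


def process_yield(inp: YieldInput) -> float:
    """Deposition efficiency gamma from the LOD-corrected mass balance:

        gamma = (m_f (1 - LOD_f) - m_s (1 - LOD_s)) / (m_susp * omega)

    LODs are accepted in percent and converted internally. Values above 1
    are returned as computed with a YieldWarning: they signal an
    inconsistent mass balance, not a computational error.
    """
    dry_gain = inp.m_f * (1.0 - inp.lod_f / 100.0) - inp.m_s * (1.0 - inp.lod_s / 100.0)
    gamma = dry_gain / (inp.m_susp * inp.dry_fraction)
    if gamma > 1.0:
        warnings.warn(
            f"process yield {gamma:.4f} exceeds 1: mass balance inconsistent",
            YieldWarning,
            stacklevel=2,
        )
    return gamma


def coating_density(inp: CoatingDensityInput) -> float:
    """Film-coating density [g/cm^3] from the shell geometry of the film.

    The dry matter actually transferred to the pellets, yield-corrected as
    gamma * m_susp_sprayed * omega, fills N = N_m * m_cores spherical shells
    of thickness h on the monodisperse-equivalent core radius
    r0 = sqrt(SSA_m / (4 pi N_m)):

        rho = gamma * m_susp * omega / (N * (4 pi / 3) ((r0 + h)^3 - r0^3))
    """
    r0 = monodisperse_radius(inp.ssa_m_core, inp.n_per_mass)
    n_pellets = inp.n_per_mass * inp.m_cores * _MG_PER_G
    dep_mg = inp.process_yield * inp.m_susp_sprayed * _MG_PER_G * inp.dry_fraction
    rho_mg_um3 = dep_mg / (n_pellets * shell_volume(r0, inp.thickness))
    return rho_mg_um3 * _G_CM3_PER_MG_UM3


def release_factor(ssa_m_sr: float, rho: float, h: float) -> float:
    """Release-rate screening factor SSA_m / (rho * h).

    Combines the film surface per mass of the coated pellets [um^2/mg], the
    film density [g/cm^3] standing in (inversely) for permeability, and the
    film thickness [um]. Only relative ordering between runs is meaningful.
    """
    if ssa_m_sr <= 0:
        raise ValueError("ssa_m_sr must be positive")
    if rho <= 0 or h <= 0:
        raise ValueError("rho and h must be positive (zero denominator)")
    return ssa_m_sr / (rho * h)
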