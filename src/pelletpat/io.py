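"""Versioned CSV readers/writers for the pipeline's table formats.

Every file starts with a comment line ``# pelletpat <kind> v1`` so formats
can evolve; readers accept files with or without the header. Formats:

- frames:   time_min, d50_um, se_um, n
- lod:      time_min, lod_pct
- profiles: time_h, pct_released, run     (long form, one row per sample)
- records:  exp, load_g, inlet_gkg, lod_start_pct, lod_finish_pct,
            yield_pct, susp_g, endpoint_mode, endpoint_time_min,
            final_thickness_um
- matrix:   run labels as header and index
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dissolution import F2Matrix
from .types import (
    CoatingRunConfig,
    DissolutionProfile,
    LODTrajectory,
    ProcessRecord,
    SizeFrame,
)

__all__ = [
    "write_frames", "read_frames",
    "write_lod", "read_lod",
    "write_profiles", "read_profiles",
    "write_records", "read_records",
    "write_matrix", "read_matrix",
    "load_config", "save_config",
]


def _write_csv(df: pd.DataFrame, path: Path, kind: str, index: bool = False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# pelletpat {kind} v1\n")
        df.to_csv(fh, index=index)


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def write_frames(frames: Sequence[SizeFrame], path: Path) -> None:
    df = pd.DataFrame(
        {
            "time_min": [f.time for f in frames],
            "d50_um": [f.d50 for f in frames],
            "se_um": [f.se for f in frames],
            "n": [f.n for f in frames],
        }
    )
    _write_csv(df, path, "frames")


def read_frames(path: Path) -> list[SizeFrame]:
    df = _read_csv(path)
    return [
        SizeFrame(time=r.time_min, d50=r.d50_um, se=r.se_um, n=int(r.n))
        for r in df.itertuples()
    ]


def write_lod(lod: LODTrajectory, path: Path) -> None:
    _write_csv(
        pd.DataFrame({"time_min": lod.times, "lod_pct": lod.values}), path, "lod"
    )


def read_lod(path: Path) -> LODTrajectory:
    df = _read_csv(path)
    return LODTrajectory(
        times=df["time_min"].to_numpy(), values=df["lod_pct"].to_numpy()
    )


def write_profiles(profiles: Sequence[DissolutionProfile], path: Path) -> None:
    rows = [
        {"time_h": t, "pct_released": r, "run": p.run}
        for p in profiles
        for t, r in zip(p.times, p.released)
    ]
    _write_csv(pd.DataFrame(rows), path, "profiles")


def read_profiles(path: Path) -> list[DissolutionProfile]:
    df = _read_csv(path)
    out = []
    for run, grp in df.groupby("run", sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            DissolutionProfile(
                run=str(run),
                times=grp["time_h"].to_numpy(),
                released=grp["pct_released"].to_numpy(),
            )
        )
    return out


def write_records(records: Sequence[ProcessRecord], path: Path) -> None:
    df = pd.DataFrame(
        {
            "exp": [r.exp for r in records],
            "load_g": [r.load_g for r in records],
            "inlet_gkg": [r.inlet_gkg for r in records],
            "lod_start_pct": [r.lod_start_pct for r in records],
            "lod_finish_pct": [r.lod_finish_pct for r in records],
            "yield_pct": [100.0 * r.yield_fraction for r in records],
            "susp_g": [r.suspension_g for r in records],
            "endpoint_mode": [r.endpoint_mode for r in records],
            "endpoint_time_min": [r.endpoint_time_min for r in records],
            "final_thickness_um": [r.final_thickness_um for r in records],
        }
    )
    _write_csv(df, path, "records")


def read_records(path: Path) -> list[ProcessRecord]:
    df = _read_csv(path)
    out = []
    for r in df.itertuples():
        t = r.endpoint_time_min
        out.append(
            ProcessRecord(
                exp=str(r.exp),
                load_g=r.load_g,
                inlet_gkg=r.inlet_gkg,
                lod_start_pct=r.lod_start_pct,
                lod_finish_pct=r.lod_finish_pct,
                yield_fraction=r.yield_pct / 100.0,
                suspension_g=r.susp_g,
                endpoint_mode=str(r.endpoint_mode),
                endpoint_time_min=None if pd.isna(t) else float(t),
                final_thickness_um=r.final_thickness_um,
            )
        )
    return out


def write_matrix(matrix: F2Matrix, path: Path) -> None:
    _write_csv(matrix.values, path, "f2-matrix", index=True)


def read_matrix(path: Path, threshold: float = 50.0) -> F2Matrix:
    df = _read_csv(path, index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return F2Matrix(values=df, threshold=threshold)


def load_config(path: Path) -> CoatingRunConfig:
    """Read a simulator configuration from a flat key/value YAML file.

    Keys mirror CoatingRunConfig fields; unknown keys are reported by name.
    """
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key/value mapping")
    valid = {f.name for f in CoatingRunConfig.__dataclass_fields__.values()}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    if "frame_particle_count_range" in data:
        data["frame_particle_count_range"] = tuple(
            data["frame_particle_count_range"]
        )
    return CoatingRunConfig(**data)


def save_config(config: CoatingRunConfig, path: Path) -> None:
    data = {
        f.name: getattr(config, f.name)
        for f in CoatingRunConfig.__dataclass_fields__.values()
    }
    data["frame_particle_count_range"] = list(data["frame_particle_count_range"])
    with Path(path).open("w") as fh:
        fh.write("# pelletpat config v1\n")
        yaml.safe_dump(data, fh, sort_keys=True)
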