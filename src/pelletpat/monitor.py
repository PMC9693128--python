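"""In-line coating-thickness estimation from D50 frame series and
process endpoint detection.

The estimator is the instrument's rule: thickness at time t is half the
difference between the frame's median particle diameter and a reference
median taken as the lowest D50 observed in the initial minutes of the run
(the attrition/shrinkage dip). The standard error combines the reference
and current frame SEs as 0.5*sqrt(SE_ref^2 + SE_t^2). Negative thickness
(shrinkage below the reference) is reported, not clipped, so the dip stays
visible in the series.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .types import ReferenceSelection, SizeFrame, ThicknessPoint

__all__ = ["find_reference", "thickness_series", "detect_endpoint"]


def _check_frames(frames: Sequence[SizeFrame]) -> None:
    times = [f.time for f in frames]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("frames must be strictly ordered in time")


def find_reference(
    frames: Sequence[SizeFrame], window: float = 10.0
) -> ReferenceSelection:
    """Select the reference frame: minimum D50 within the first `window`
    minutes; the earliest frame wins ties.
    """
    _check_frames(frames)
    candidates = [f for f in frames if f.time <= window]
    if not candidates:
        raise ValueError(f"no frames within the {window} min reference window")
    best = min(candidates, key=lambda f: (f.d50, f.time))
    return ReferenceSelection(time=best.time, d50=best.d50, se=best.se, window=window)


def thickness_series(
    frames: Sequence[SizeFrame], ref: ReferenceSelection
) -> list[ThicknessPoint]:
    """Coating-thickness estimates (D50(t) - D50_ref) / 2 with propagated SE
    0.5*sqrt(SE_ref^2 + SE_t^2) for every frame."""
    _check_frames(frames)
    if not any(
        abs(f.time - ref.time) < 1e-9 and f.d50 == ref.d50 for f in frames
    ):
        raise ValueError("reference selection was not drawn from these frames")
    return [
        ThicknessPoint(
            time=f.time,
            thickness=(f.d50 - ref.d50) / 2.0,
            se=0.5 * (ref.se**2 + f.se**2) ** 0.5,
        )
        for f in frames
    ]


def detect_endpoint(
    series: Sequence[ThicknessPoint],
    target: float,
    consecutive: int = 1,
) -> Optional[float]:
    """Time of the process endpoint: the first point whose thickness reaches
    the target (>=, so an exact hit counts). With consecutive=k > 1, the
    endpoint is the first of k successive points all at or above target —
    a guard against single-frame outliers; the default k=1 stops at the
    first crossing, matching manual operation. Returns None if the target
    is never reached.
    """
    if target <= 0:
        raise ValueError("target thickness must be positive")
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    run = 0
    for i, p in enumerate(series):
        run = run + 1 if p.thickness >= target else 0
        if run >= consecutive:
            return series[i - consecutive + 1].time
    return None
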