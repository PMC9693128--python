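"""Dissolution-profile analytics: f2 similarity, pairwise similarity
matrices and grouping, and correlation screening of the 6 h release
against process/material covariates.

The f2 similarity factor between release profiles R and T sampled on the
same n time points is

    f2 = 50 * log10( 100 / sqrt(1 + mean((R_t - T_t)^2)) )

f2 = 100 for identical profiles; two profiles are conventionally deemed
similar when f2 is between 50 and 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import DissolutionProfile

__all__ = [
    "f2",
    "F2Matrix",
    "f2_matrix",
    "group_by_similarity",
    "correlate",
    "SIMILARITY_THRESHOLD",
]

SIMILARITY_THRESHOLD = 50.0


def f2(
    profile1: DissolutionProfile,
    profile2: DissolutionProfile,
    truncate_after_85: bool = False,
) -> float:
    """Similarity factor f2 between two profiles on identical time grids.

    By default every sampled time point enters the statistic. With
    truncate_after_85=True, points after both profiles have passed 85 %
    release are dropped (keeping the first such point), the regulatory
    convention for fast-releasing products.
    """
    if len(profile1) != len(profile2) or not np.allclose(
        profile1.times, profile2.times
    ):
        raise ValueError("profiles must share an identical time grid")
    r, t = profile1.released, profile2.released
    if truncate_after_85:
        past = (r > 85.0) & (t > 85.0)
        if past.any():
            keep = max(1, int(np.argmax(past)) + 1)
            r, t = r[:keep], t[:keep]
    msd = float(np.mean((r - t) ** 2))
    return 50.0 * math.log10(100.0 / math.sqrt(1.0 + msd))


@dataclass(frozen=True)
class F2Matrix:
    """Symmetric pairwise f2 table; the diagonal is undefined (NaN)."""

    values: pd.DataFrame
    threshold: float = SIMILARITY_THRESHOLD

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def similar(self) -> pd.DataFrame:
        """Boolean table of pairs at or above the similarity threshold."""
        return self.values >= self.threshold


def f2_matrix(
    profiles: Sequence[DissolutionProfile],
    threshold: float = SIMILARITY_THRESHOLD,
    truncate_after_85: bool = False,
) -> F2Matrix:
    """All pairwise f2 values between the given profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for a similarity matrix")
    labels = [p.run for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("profile run labels must be unique")
    n = len(profiles)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = f2(
                profiles[i], profiles[j], truncate_after_85=truncate_after_85
            )
    return F2Matrix(
        values=pd.DataFrame(mat, index=labels, columns=labels),
        threshold=threshold,
    )


def group_by_similarity(matrix: F2Matrix) -> list[list[str]]:
    """Partition runs into connected components of the similarity graph
    (edges where f2 >= threshold). Groups are ordered by their first member's
    position in the matrix; members keep matrix order — deterministic for a
    given matrix.
    """
    labels = matrix.labels
    index = {lab: i for i, lab in enumerate(labels)}
    sim = matrix.similar().to_numpy()
    parent = list(range(len(labels)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if sim[i, j]:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for lab in labels:
        groups.setdefault(find(index[lab]), []).append(lab)
    return sorted(groups.values(), key=lambda g: index[g[0]])


def correlate(
    table: pd.DataFrame,
    response: str = "released_6h",
    covariates: Optional[Sequence[str]] = None,
    strong: float = 0.9,
) -> pd.DataFrame:
    """Pearson correlation of each covariate against the response.

    `table` holds one row per run; `covariates` defaults to every numeric
    column except the response. Constant covariates have an undefined
    coefficient and are reported with K = NaN. Returns a DataFrame indexed
    by covariate with columns K (the coefficient) and strong
    (|K| > `strong`, NaN-safe False).
    """
    if response not in table.columns:
        raise ValueError(f"response column {response!r} missing")
    if len(table) < 3:
        raise ValueError("need at least 3 runs to screen correlations")
    y = table[response].to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("response must have no missing values")
    if covariates is None:
        covariates = [
            c
            for c in table.columns
            if c != response and np.issubdtype(table[c].dtype, np.number)
        ]
    rows = []
    yc = y - y.mean()
    sy = math.sqrt(float(yc @ yc))
    for cov in covariates:
        x = table[cov].to_numpy(dtype=float)
        xc = x - x.mean()
        sx = math.sqrt(float(xc @ xc))
        k = float(xc @ yc) / (sx * sy) if sx > 0 and sy > 0 else math.nan
        rows.append({"covariate": cov, "K": k, "strong": bool(abs(k) > strong)
                     if not math.isnan(k) else False})
    return pd.DataFrame(rows).set_index("covariate")
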