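"""Reflection bookkeeping and merging statistics under Laue symmetry.

Supports the triclinic Laue group -1 (Friedel only) and tetragonal
4/mmm.  Observations live in a pandas DataFrame with columns
``h k l frame intensity sigma`` and an optional ``tilt``; tables are read
and written as whitespace-delimited text with that header line.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UnitCell",
    "MergeStats",
    "laue_operations",
    "map_to_asu",
    "d_spacing",
    "generate_unique_set",
    "merge_stats",
    "read_reflection_table",
    "write_reflection_table",
]

REQUIRED_COLUMNS = ("h", "k", "l", "frame", "intensity", "sigma")


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        if (self.alpha, self.beta, self.gamma) != (90.0, 90.0, 90.0):
            raise ValueError("only orthogonal cells (all angles 90) are supported")

    def require_tetragonal(self) -> None:
        if self.a != self.b:
            raise ValueError(
                f"tetragonal symmetry requires a = b, got a={self.a}, b={self.b}"
            )


# Rotational point-group operations as (h,k,l) index maps; Friedel
# inversion is applied on top of these in map_to_asu.
_LAUE_ROTATIONS = {
    "-1": [lambda h, k, l: (h, k, l)],
    # 422: identity, 4+, 4-, 2(c), 2(a), 2(b), 2(110), 2(1-10)
    "4/mmm": [
        lambda h, k, l: (h, k, l),
        lambda h, k, l: (-k, h, l),
        lambda h, k, l: (k, -h, l),
        lambda h, k, l: (-h, -k, l),
        lambda h, k, l: (h, -k, -l),
        lambda h, k, l: (-h, k, -l),
        lambda h, k, l: (k, h, -l),
        lambda h, k, l: (-k, -h, -l),
    ],
}


def laue_operations(laue_group: str):
    """All index-space operations of a Laue group, inversion included."""
    if laue_group not in _LAUE_ROTATIONS:
        raise ValueError(
            f"unsupported Laue group {laue_group!r}; "
            f"supported groups: {sorted(_LAUE_ROTATIONS)}"
        )
    rotations = _LAUE_ROTATIONS[laue_group]
    ops = []
    for rot in rotations:
        ops.append(rot)
        ops.append(lambda h, k, l, _r=rot: tuple(-x for x in _r(h, k, l)))
    return ops


def map_to_asu(h: int, k: int, l: int, laue_group: str) -> tuple[int, int, int]:
    """Canonical asymmetric-unit representative of (h, k, l).

    Applies every Laue operation (rotations plus Friedel inversion) and
    returns the lexicographically greatest equivalent index triple.
    """
    return max(op(h, k, l) for op in laue_operations(laue_group))


def d_spacing(cell: UnitCell, h: int, k: int, l: int) -> float:
    """Resolution of a reflection in an orthogonal cell:
    1/d^2 = h^2/a^2 + k^2/b^2 + l^2/c^2."""
    inv_d2 = (h / cell.a) ** 2 + (k / cell.b) ** 2 + (l / cell.c) ** 2
    if inv_d2 == 0:
        raise ValueError("(0,0,0) has no resolution")
    return inv_d2**-0.5


def generate_unique_set(
    cell: UnitCell, d_min: float, laue_group: str
) -> set[tuple[int, int, int]]:
    """All symmetry-unique reflections with d >= d_min, excluding (0,0,0)."""
    return set(_unique_set_cached(cell, d_min, laue_group))


@lru_cache(maxsize=64)
def _unique_set_cached(
    cell: UnitCell, d_min: float, laue_group: str
) -> frozenset[tuple[int, int, int]]:
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if laue_group == "4/mmm":
        cell.require_tetragonal()
    h_max = int(cell.a / d_min)
    k_max = int(cell.b / d_min)
    l_max = int(cell.c / d_min)
    unique: set[tuple[int, int, int]] = set()
    for h in range(-h_max, h_max + 1):
        for k in range(-k_max, k_max + 1):
            for l in range(-l_max, l_max + 1):
                if h == k == l == 0:
                    continue
                if d_spacing(cell, h, k, l) >= d_min:
                    unique.add(map_to_asu(h, k, l, laue_group))
    return frozenset(unique)


@dataclass(frozen=True)
class MergeStats:
    n_observations: int
    n_unique: int
    multiplicity: float
    completeness: float
    r_merge: float
    cc_half: float
    mean_i_over_sigma: float


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"reflection table is missing columns {missing}")
    if len(table) == 0:
        raise ValueError("reflection table is empty")
    if (table["sigma"] <= 0).any():
        raise ValueError("all sigma values must be positive")
    return table


def merge_stats(
    table: pd.DataFrame,
    cell: UnitCell,
    laue_group: str,
    d_min: float,
    seed: int = 0,
) -> MergeStats:
    """Merge a reflection table and compute the standard quality statistics.

    R_merge = sum_hkl sum_i |I_i - <I>| / sum_hkl sum_i I_i over all
    observations; CC1/2 is the Pearson correlation between the mean
    intensities of two random half-data-sets (seeded split); groups with a
    single observation contribute nothing to the R_merge numerator and are
    excluded from CC1/2.  Negative intensities are retained throughout.
    """
    table = _validate_table(table)
    d = np.array(
        [d_spacing(cell, h, k, l) for h, k, l in zip(table["h"], table["k"], table["l"])]
    )
    table = table.loc[d >= d_min]
    if len(table) == 0:
        raise ValueError(f"no observations at d >= {d_min} A")
    asu = [
        map_to_asu(int(h), int(k), int(l), laue_group)
        for h, k, l in zip(table["h"], table["k"], table["l"])
    ]
    intensities = table["intensity"].to_numpy(dtype=float)
    sigmas = table["sigma"].to_numpy(dtype=float)

    groups: dict[tuple[int, int, int], list[int]] = {}
    for idx, key in enumerate(asu):
        groups.setdefault(key, []).append(idx)

    n_obs = len(table)
    n_unique = len(groups)
    unique_set = generate_unique_set(cell, d_min, laue_group)
    completeness = len(set(groups) & unique_set) / len(unique_set) if unique_set else 0.0

    numerator = 0.0
    denominator = float(np.sum(intensities))
    rng = np.random.default_rng(seed)
    half1, half2 = [], []
    for indices in groups.values():
        vals = intensities[indices]
        if len(vals) >= 2:
            numerator += float(np.sum(np.abs(vals - vals.mean())))
            perm = rng.permutation(len(vals))
            mid = len(vals) // 2
            half1.append(float(vals[perm[:mid]].mean()))
            half2.append(float(vals[perm[mid:]].mean()))
    r_merge = numerator / denominator if denominator != 0 else float("nan")
    if len(half1) >= 2 and np.std(half1) > 0 and np.std(half2) > 0:
        cc_half = float(np.corrcoef(half1, half2)[0, 1])
    elif len(half1) >= 1 and np.allclose(half1, half2):
        cc_half = 1.0  # zero-spread data correlate perfectly
    else:
        cc_half = float("nan")
    return MergeStats(
        n_observations=n_obs,
        n_unique=n_unique,
        multiplicity=n_obs / n_unique,
        completeness=completeness,
        r_merge=r_merge,
        cc_half=cc_half,
        mean_i_over_sigma=float(np.mean(intensities / sigmas)),
    )


def read_reflection_table(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited reflection table with a header line."""
    table = pd.read_csv(path, sep=r"\s+")
    return _validate_table(table)


def write_reflection_table(table: pd.DataFrame, path: str | Path) -> None:
    _validate_table(table)
    table.to_csv(path, sep=" ", index=False, float_format="%.8g")
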