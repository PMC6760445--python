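"""Radiation-damage analytics: dose-decay fitting, D50, completeness curves.

The central model is a shared exponential decay of the per-frame mean
integrated intensity,

    y_ci = A_c * exp(-B * x_ci),

where ``A_c`` is refined per crystal and the decay constant ``B`` is
shared across all crystals measured on one camera.  The half-intensity
exposure is D50 = ln(2) / B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from microed_tools.geometry import ExposureLedger
from microed_tools.reflection_tools import (
    UnitCell,
    d_spacing,
    generate_unique_set,
    merge_stats,
)

__all__ = [
    "IntensitySeries",
    "DecayModel",
    "CompletenessCurve",
    "EmptySeriesError",
    "FitError",
    "CompletenessNotAttainedError",
    "frame_mean_intensity",
    "fit_shared_decay",
    "d50",
    "completeness_vs_exposure",
    "exposure_at_completeness",
    "fit_rocking_curve",
]


class EmptySeriesError(ValueError):
    """Every observation was removed by the tilt/resolution filters."""


class FitError(RuntimeError):
    """The nonlinear fit failed to converge."""


class CompletenessNotAttainedError(ValueError):
    def __init__(self, target: float, max_completeness: float) -> None:
        self.target = target
        self.max_completeness = max_completeness
        super().__init__(
            f"completeness target {target:.3f} never reached "
            f"(maximum attained: {max_completeness:.3f})"
        )


@dataclass
class IntensitySeries:
    """Mean integrated intensity per frame versus cumulative exposure."""

    crystal_id: str
    x: np.ndarray  # exposures, e-/A^2, strictly increasing
    y: np.ndarray  # mean intensities, arbitrary scale
    filters_applied: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("exposures must be strictly increasing")


@dataclass
class DecayModel:
    """Fitted shared-decay model: per-crystal amplitudes and one decay constant."""

    A: dict[str, float]
    B: float
    no_decay_warning: bool = False

    @property
    def D50(self) -> float:
        return d50(self)


def d50(model: DecayModel) -> float:
    """Exposure at which intensity falls to half its zero-dose extrapolation."""
    if model.B <= 0:
        raise ValueError(f"D50 is undefined for B = {model.B} (no decay)")
    return float(np.log(2.0) / model.B)


def frame_mean_intensity(
    table: pd.DataFrame,
    ledger: ExposureLedger,
    cell: UnitCell,
    tilt_range: tuple[float, float] = (-30.0, 30.0),
    resolution_range: tuple[float, float] = (2.70, 20.0),
    crystal_id: str = "crystal",
) -> IntensitySeries:
    """Per-frame mean intensity after tilt and resolution filtering.

    Observations with tilt in the closed ``tilt_range`` interval and
    d-spacing in the closed ``resolution_range`` interval (low, high in A)
    are kept; frames with no surviving observations are omitted from the
    series.  Frame indices are 0-based into the ledger.
    """
    if "tilt" not in table.columns:
        raise ValueError("table has no 'tilt' column; cannot apply the tilt filter")
    lo_t, hi_t = tilt_range
    lo_d, hi_d = min(resolution_range), max(resolution_range)
    if lo_t >= hi_t:
        raise ValueError("tilt_range must satisfy low < high")
    d = np.array(
        [d_spacing(cell, h, k, l) for h, k, l in zip(table["h"], table["k"], table["l"])]
    )
    keep = (
        (table["tilt"] >= lo_t)
        & (table["tilt"] <= hi_t)
        & (d >= lo_d)
        & (d <= hi_d)
    )
    kept = table.loc[keep]
    if len(kept) == 0:
        raise EmptySeriesError("all observations removed by tilt/resolution filters")
    means = kept.groupby("frame")["intensity"].mean()
    frames = means.index.to_numpy(dtype=int)
    if frames.min() < 0 or frames.max() >= ledger.n_frames:
        raise ValueError(
            f"frame indices [{frames.min()}, {frames.max()}] outside ledger "
            f"of {ledger.n_frames} frames"
        )
    return IntensitySeries(
        crystal_id=crystal_id,
        x=ledger.cumulative_exposure[frames],
        y=means.to_numpy(dtype=float),
        filters_applied={
            "tilt_range": (lo_t, hi_t),
            "resolution_range": (lo_d, hi_d),
        },
    )


def fit_shared_decay(series_list: list[IntensitySeries]) -> DecayModel:
    """Fit A_c * exp(-B x) with per-series amplitude and shared B.

    Nonlinear least squares in linear intensity space, initialized from a
    pooled log-linear regression (per-series intercepts, common slope).
    """
    if not series_list:
        raise ValueError("need at least one series")
    for s in series_list:
        if len(s.x) < 3:
            raise ValueError(
                f"series {s.crystal_id!r} has {len(s.x)} points; >= 3 required"
            )
    ids = [s.crystal_id for s in series_list]
    if len(set(ids)) != len(ids):
        ids = [f"{cid}#{i}" for i, cid in enumerate(ids)]

    # Log-space initializer: design matrix with one intercept per series
    # and a common slope -B.  Requires y > 0; fall back to crude moments
    # if not.
    n_series = len(series_list)
    all_pos = all(np.all(s.y > 0) for s in series_list)
    if all_pos:
        rows, cols, logy = [], [], []
        for j, s in enumerate(series_list):
            for xi, yi in zip(s.x, s.y):
                rows.append((j, xi))
                logy.append(np.log(yi))
        design = np.zeros((len(rows), n_series + 1))
        for i, (j, xi) in enumerate(rows):
            design[i, j] = 1.0
            design[i, n_series] = -xi
        coef, *_ = np.linalg.lstsq(design, np.array(logy), rcond=None)
        a0 = np.exp(coef[:n_series])
        b0 = float(coef[n_series])
    else:
        a0 = np.array([max(float(s.y[0]), 1e-12) for s in series_list])
        b0 = 0.1

    def residuals(params: np.ndarray) -> np.ndarray:
        amps, b = params[:n_series], params[n_series]
        return np.concatenate(
            [s.y - amps[j] * np.exp(-b * s.x) for j, s in enumerate(series_list)]
        )

    result = least_squares(
        residuals,
        np.concatenate([a0, [b0]]),
        method="lm",
        xtol=1e-14,
        ftol=1e-14,
        max_nfev=10000,
    )
    if not result.success:
        raise FitError(f"shared-decay fit did not converge: {result.message}")
    amps, b = result.x[:n_series], float(result.x[n_series])
    no_decay = b <= 1e-10
    if no_decay:
        warnings.warn(
            f"fitted decay constant B = {b:.3g} <= 0: no damage detectable",
            RuntimeWarning,
            stacklevel=2,
        )
    return DecayModel(
        A={cid: float(a) for cid, a in zip(ids, amps)},
        B=b,
        no_decay_warning=no_decay,
    )


@dataclass
class CompletenessCurve:
    exposure_cutoffs: np.ndarray
    completeness: np.ndarray
    multiplicity: np.ndarray

    def __post_init__(self) -> None:
        self.exposure_cutoffs = np.asarray(self.exposure_cutoffs, dtype=float)
        self.completeness = np.asarray(self.completeness, dtype=float)
        self.multiplicity = np.asarray(self.multiplicity, dtype=float)


def completeness_vs_exposure(
    table: pd.DataFrame,
    ledger: ExposureLedger,
    cell: UnitCell,
    laue_group: str,
    d_min: float,
    cutoffs,
    seed: int = 0,
) -> CompletenessCurve:
    """Completeness and multiplicity when merging only frames below each cutoff.

    A frame is included when its (end-of-frame) cumulative exposure is
    strictly less than the cutoff.
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if np.any(np.diff(cutoffs) < 0):
        raise ValueError("cutoffs must be sorted ascending")
    exposure_of_frame = ledger.cumulative_exposure
    frames = table["frame"].to_numpy(dtype=int)
    completeness, multiplicity = [], []
    for cutoff in cutoffs:
        included = exposure_of_frame[frames] < cutoff
        sub = table.loc[included]
        if len(sub) == 0:
            completeness.append(0.0)
            multiplicity.append(0.0)
            continue
        stats = merge_stats(sub, cell, laue_group, d_min, seed=seed)
        completeness.append(stats.completeness)
        multiplicity.append(stats.multiplicity)
    return CompletenessCurve(cutoffs, completeness, multiplicity)


def exposure_at_completeness(curve: CompletenessCurve, target: float) -> float:
    """Smallest exposure at which completeness reaches ``target``.

    Linearly interpolated between the bracketing cutoffs; raises
    CompletenessNotAttainedError if the curve never reaches the target.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    comp = curve.completeness
    if comp.size == 0:
        raise ValueError("curve is empty")
    if target > 1:  # impossible by definition of completeness
        raise CompletenessNotAttainedError(target, float(comp.max()))
    above = np.nonzero(comp >= target)[0]
    if above.size == 0:
        raise CompletenessNotAttainedError(target, float(comp.max()))
    i = int(above[0])
    if i == 0 or comp[i] == target:
        return float(curve.exposure_cutoffs[i])
    x0, x1 = curve.exposure_cutoffs[i - 1], curve.exposure_cutoffs[i]
    y0, y1 = comp[i - 1], comp[i]
    return float(x0 + (target - y0) / (y1 - y0) * (x1 - x0))


def fit_rocking_curve(
    per_frame_intensities,
) -> tuple[float, float, float]:
    """Weighted Gaussian fit of a reflection's intensity versus rotation angle.

    Input is a sequence of (angle_deg, intensity, sigma) triples; sigma
    may be None/NaN for unweighted fitting.  Returns (center, width,
    height) of I(phi) = h * exp(-(phi - c)^2 / (2 w^2)).
    """
    pts = np.asarray(
        [(a, i, s if s is not None else np.nan) for a, i, s in per_frame_intensities],
        dtype=float,
    )
    if pts.shape[0] < 4:
        raise ValueError(f"need at least 4 points, got {pts.shape[0]}")
    angles, intens, sig = pts[:, 0], pts[:, 1], pts[:, 2]
    weights = None if np.any(~np.isfinite(sig)) else sig

    spacing = float(np.min(np.diff(np.sort(angles))))
    pos = np.clip(intens, 0, None)
    total = pos.sum()
    if total <= 0:
        raise ValueError("no positive intensity to fit")
    c0 = float(np.sum(angles * pos) / total)
    var0 = float(np.sum((angles - c0) ** 2 * pos) / total)
    if var0 < (spacing / 2.0) ** 2:
        warnings.warn(
            "intensity concentrated on a single frame; "
            "width floored at half the frame spacing",
            RuntimeWarning,
            stacklevel=2,
        )
        return c0, spacing / 2.0, float(intens.max())
    w0 = np.sqrt(var0)

    def model(phi, h, c, w):
        return h * np.exp(-((phi - c) ** 2) / (2.0 * w**2))

    popt, _ = curve_fit(
        model,
        angles,
        intens,
        p0=[float(intens.max()), c0, w0],
        sigma=weights,
        absolute_sigma=weights is not None,
        maxfev=10000,
    )
    height, center, width = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    return center, width, height
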