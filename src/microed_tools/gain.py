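"""Detector gain estimation from Poisson background statistics.

If every primary electron event deposits ``G`` ADU, background pixel
values are ``G * Poisson(n)``, so variance/mean of the background equals
``G`` (the index of dispersion).  Bragg spots are suppressed by keeping
only pixels at or below a brightness quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["GainEstimate", "GainEstimationError", "estimate_gain"]

_MIN_PIXELS = 1000


class GainEstimationError(ValueError):
    """Background statistics are unusable (e.g. mis-specified pedestal)."""


@dataclass(frozen=True)
class GainEstimate:
    """Method-of-moments gain estimate with its background diagnostics."""

    G: float
    background_mean: float
    background_variance: float
    n_pixels_used: int


def estimate_gain(
    frame: np.ndarray,
    pedestal: float = 0.0,
    spot_exclusion_quantile: float = 0.99,
    read_noise_var: float = 0.0,
    mask: np.ndarray | None = None,
) -> GainEstimate:
    """Estimate the gain G = var/mean of background pixels.

    Parameters
    ----------
    frame : 2-D pixel array (a single detector frame).
    pedestal : constant already added to the raw values; subtracted before
        estimation.
    spot_exclusion_quantile : pixels above this brightness quantile are
        excluded as candidate Bragg spots; 1.0 keeps everything.
    read_noise_var : known Gaussian read-noise variance (ADU^2), subtracted
        from the background variance to de-bias the estimate.
    mask : optional boolean array, True for pixels to consider.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size < _MIN_PIXELS:
        raise ValueError(
            f"frame must contain at least {_MIN_PIXELS} pixels, got {frame.size}"
        )
    if not 0.0 <= spot_exclusion_quantile <= 1.0:
        raise ValueError("spot_exclusion_quantile must lie in [0, 1]")
    values = frame[mask] if mask is not None else frame.ravel()
    values = values - pedestal
    if spot_exclusion_quantile < 1.0:
        cutoff = np.quantile(values, spot_exclusion_quantile)
        values = values[values <= cutoff]
    mean = float(values.mean())
    variance = float(values.var(ddof=1)) - read_noise_var
    if mean <= 0:
        raise GainEstimationError(
            f"background mean after pedestal subtraction is {mean:.3g} <= 0; "
            "the pedestal is probably mis-specified"
        )
    if variance <= 0:
        warnings.warn(
            "degenerate background statistics: variance <= 0, gain estimate is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        variance = max(variance, 0.0)
    return GainEstimate(
        G=variance / mean,
        background_mean=mean,
        background_variance=variance,
        n_pixels_used=int(values.size),
    )
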