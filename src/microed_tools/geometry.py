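"""Diffraction-geometry arithmetic for continuous-rotation electron diffraction.

Electron wavelength, resolution at a detector radius, spot-separation
estimates, per-frame oscillation, exposure ledgers and detector
linear-range thresholds.  All lengths are explicit about units:
millimetres on the detector, Ångström in reciprocal space, micrometres
for physical pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "ExposureLedger",
    "electron_wavelength",
    "resolution_at_radius",
    "edge_resolution",
    "spot_separation_px",
    "linear_adu_threshold",
    "delta_phi_per_frame",
    "exposure_ledger",
]

# CODATA 2018 exact / recommended values.
_PLANCK_H = 6.62607015e-34  # J s
_ELECTRON_MASS = 9.1093837015e-31  # kg
_ELEMENTARY_CHARGE = 1.602176634e-19  # C
_SPEED_OF_LIGHT = 299792458.0  # m/s


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength of an electron in Ångström.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2)))

    Parameters
    ----------
    voltage_kv : acceleration voltage in kilovolts; must be > 0.
    """
    if voltage_kv <= 0:
        raise ValueError(f"voltage must be positive, got {voltage_kv} kV")
    volts = voltage_kv * 1e3
    rest_energy = _ELECTRON_MASS * _SPEED_OF_LIGHT**2
    p = math.sqrt(
        2.0
        * _ELECTRON_MASS
        * _ELEMENTARY_CHARGE
        * volts
        * (1.0 + _ELEMENTARY_CHARGE * volts / (2.0 * rest_energy))
    )
    return _PLANCK_H / p * 1e10


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Camera and microscope parameters a data set was collected with.

    ``distance_mm`` is the *virtual* sample-to-detector distance: the
    physical distance of an equivalent lensless system.  ``exposure_rate``
    is incident fluence per unit time in e- / A^2 / s.
    """

    voltage_kv: float
    distance_mm: float
    physical_pixel_um: float = 14.0
    binning: int = 1
    frame_shape: tuple[int, int] = (2048, 2048)
    rotation_speed_deg_s: float = 0.0
    exposure_time_s: float = 1.0
    exposure_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.voltage_kv <= 0:
            raise ValueError("voltage_kv must be > 0")
        if self.distance_mm <= 0:
            raise ValueError("distance_mm must be > 0")
        if self.physical_pixel_um <= 0:
            raise ValueError("physical_pixel_um must be > 0")
        if self.binning < 1:
            raise ValueError("binning must be >= 1")
        if self.exposure_time_s <= 0:
            raise ValueError("exposure_time_s must be > 0")
        if self.rotation_speed_deg_s < 0:
            raise ValueError("rotation_speed_deg_s must be >= 0")

    @property
    def pixel_size_mm(self) -> float:
        """Binned pixel edge on the detector, in mm."""
        return self.physical_pixel_um * self.binning / 1000.0

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage_kv)


def resolution_at_radius(geom: AcquisitionGeometry, radius_mm: float) -> float:
    """Bragg d-spacing (A) recorded at ``radius_mm`` from the beam centre.

    Uses the exact relation d = lambda / (2 sin theta) with
    2 theta = atan(r / D); no small-angle approximation.
    """
    if radius_mm <= 0:
        raise ValueError(f"radius must be positive, got {radius_mm} mm")
    two_theta = math.atan2(radius_mm, geom.distance_mm)
    return geom.wavelength / (2.0 * math.sin(two_theta / 2.0))


def edge_resolution(geom: AcquisitionGeometry) -> float:
    """d-spacing at the detector edge: half-width along the shorter frame axis."""
    radius_mm = (min(geom.frame_shape) / 2.0) * geom.pixel_size_mm
    return resolution_at_radius(geom, radius_mm)


def spot_separation_px(
    cell_edge_a: float, d_min: float, half_width_px: float
) -> float:
    """Pixel separation of neighbouring spots along a reciprocal axis.

    When the resolution limit ``d_min`` falls at ``half_width_px`` pixels
    from the beam centre, the reciprocal-lattice row spacing 1/a of a cell
    edge ``a`` maps to ``half_width_px * d_min / a`` pixels.
    """
    if cell_edge_a <= 0 or d_min <= 0 or half_width_px <= 0:
        raise ValueError("all arguments must be positive")
    if d_min >= cell_edge_a:
        raise ValueError(
            f"d_min ({d_min} A) must be smaller than the cell edge "
            f"({cell_edge_a} A); no reflections in range otherwise"
        )
    return half_width_px * d_min / cell_edge_a


def linear_adu_threshold(single_frame_limit: float, n_averaged: int) -> float:
    """Per-image linear-range limit when each stored image averages ``n_averaged`` frames."""
    if single_frame_limit <= 0:
        raise ValueError("single_frame_limit must be > 0")
    if n_averaged <= 0:
        raise ValueError("n_averaged must be > 0")
    return single_frame_limit / n_averaged


def delta_phi_per_frame(geom: AcquisitionGeometry) -> float:
    """Rotation per frame in degrees: rotation speed times per-frame exposure time."""
    return geom.rotation_speed_deg_s * geom.exposure_time_s


@dataclass(frozen=True)
class ExposureLedger:
    """Cumulative fluence bookkeeping for a movie of frames.

    ``cumulative_exposure[i]`` is the fluence accumulated by the *end* of
    frame ``i`` (0-based); ``e_max`` is the exposure of the last frame.
    """

    per_frame_exposure: float
    cumulative_exposure: np.ndarray = field(repr=False)
    e_max: float = 0.0

    def __post_init__(self) -> None:
        cum = np.asarray(self.cumulative_exposure, dtype=float)
        object.__setattr__(self, "cumulative_exposure", cum)
        if cum.size == 0:
            raise ValueError("ledger needs at least one frame")
        if np.any(np.diff(cum) <= 0):
            raise ValueError("cumulative exposure must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.cumulative_exposure.size)


def exposure_ledger(geom: AcquisitionGeometry, n_frames: int) -> ExposureLedger:
    """Build the exposure ledger for ``n_frames`` frames of a data set."""
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    per_frame = geom.exposure_rate * geom.exposure_time_s
    cum = per_frame * np.arange(1, n_frames + 1, dtype=float)
    return ExposureLedger(
        per_frame_exposure=per_frame,
        cumulative_exposure=cum,
        e_max=float(cum[-1]),
    )
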