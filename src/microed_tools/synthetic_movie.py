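"""Ground-truth diffraction-movie and reflection-table simulator.

Frames are built from the same statistical ingredients the analysis
modules assume: a Poisson background scaled by the detector gain,
Bragg spots with Poisson counting statistics spread over a Gaussian
footprint, Gaussian read noise (which produces negative pixels), an
exponential intensity decay with exposure, and a per-reflection rocking
profile.  Random streams are split per purpose so toggling one component
does not perturb the others at a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from microed_tools.frame_io import FrameStack
from microed_tools.geometry import (
    AcquisitionGeometry,
    delta_phi_per_frame,
    edge_resolution,
    exposure_ledger,
    spot_separation_px,
)
from microed_tools.reflection_tools import UnitCell, generate_unique_set

__all__ = ["SimulationConfig", "GroundTruth", "simulate_movie", "simulate_reflection_table"]


@dataclass
class SimulationConfig:
    geometry: AcquisitionGeometry
    cell: UnitCell
    laue_group: str = "4/mmm"
    n_frames: int = 10
    gain: float = 1.0
    background_rate: float = 5.0  # events / pixel / frame
    read_noise_sd: float = 0.0  # ADU
    pedestal_truth: int = 0  # offset subtracted from raw frames
    decay_B: float = 0.0  # A^2 / e-
    spot_profile_sd: float = 2.0  # pixels
    base_intensities: dict[tuple[int, int, int], float] = field(default_factory=dict)
    rocking_width_deg: float = 0.0  # 0 disables the rocking profile
    tilt_start_deg: float = 30.0  # stage rotates from high to zero tilt
    averaging_frames: int = 1  # Falcon-style subframe averaging
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if min(self.gain, self.background_rate, self.spot_profile_sd) < 0:
            raise ValueError("rates and spreads must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.averaging_frames < 1:
            raise ValueError("averaging_frames must be >= 1")


@dataclass
class GroundTruth:
    reflection_table: pd.DataFrame
    true_gain: float
    true_B: float
    true_D50: float
    clipped_fractions: list[float]
    skipped_spots: list[tuple[int, int, int]] = field(default_factory=list)


def _spot_positions(config: SimulationConfig):
    """Project (h, k, 0)-zone spots onto the detector around its centre."""
    geom = config.geometry
    rows, cols = geom.frame_shape
    d_edge = edge_resolution(geom)
    sep = spot_separation_px(config.cell.a, d_edge, min(rows, cols) / 2.0)
    center = (rows / 2.0, cols / 2.0)
    positions, skipped = {}, []
    for (h, k, l), intensity in config.base_intensities.items():
        r = center[0] + k * sep
        c = center[1] + h * sep
        if not (0 <= r < rows and 0 <= c < cols):
            skipped.append((h, k, l))
            continue
        positions[(h, k, l)] = (r, c, intensity)
    return positions, skipped


def simulate_movie(config: SimulationConfig) -> tuple[FrameStack, GroundTruth]:
    """Generate a movie stack together with its exact ground truth.

    Each frame is

        gain * Poisson(background) + spots + Normal(0, read_noise_sd)
        - pedestal_truth

    where each spot contributes ``gain`` ADU per Poisson-drawn event,
    scattered over a Gaussian footprint, with mean count
    I0 * exp(-B x) * rocking_factor.  The ground truth records every
    spot's realized integrated intensity on every frame, and the clipped
    fraction that re-applying ``pedestal_truth`` as the conversion
    pedestal would produce.
    """
    geom = config.geometry
    rows, cols = geom.frame_shape
    ss = np.random.SeedSequence(config.seed)
    bg_rng, spot_rng, noise_rng, misc_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    ledger = exposure_ledger(geom, config.n_frames)
    dphi = delta_phi_per_frame(geom)
    positions, skipped = _spot_positions(config)

    # one rocking centre per reflection, inside the covered angular range
    phi_frames = config.tilt_start_deg - dphi * np.arange(config.n_frames)
    rocking_centers = {
        hkl: misc_rng.uniform(min(phi_frames), max(phi_frames)) if dphi > 0 else 0.0
        for hkl in positions
    }

    frames = np.zeros((config.n_frames, rows, cols), dtype=np.float32)
    records = []
    avg = config.averaging_frames
    for i in range(config.n_frames):
        if config.background_rate > 0:
            counts = bg_rng.poisson(config.background_rate * avg, size=(rows, cols))
            frames[i] += config.gain * counts / avg
        x_i = ledger.cumulative_exposure[i]
        for hkl, (r0, c0, base) in positions.items():
            mean_count = base * np.exp(-config.decay_B * x_i)
            if config.rocking_width_deg > 0:
                mean_count *= np.exp(
                    -((phi_frames[i] - rocking_centers[hkl]) ** 2)
                    / (2.0 * config.rocking_width_deg**2)
                )
            n_events = spot_rng.poisson(mean_count * avg)
            if n_events > 0:
                rr = spot_rng.normal(r0, config.spot_profile_sd, n_events)
                cc = spot_rng.normal(c0, config.spot_profile_sd, n_events)
                ri = np.clip(np.rint(rr).astype(int), 0, rows - 1)
                ci = np.clip(np.rint(cc).astype(int), 0, cols - 1)
                np.add.at(frames[i], (ri, ci), config.gain / avg)
            realized = config.gain * n_events / avg
            records.append(
                {
                    "h": hkl[0],
                    "k": hkl[1],
                    "l": hkl[2],
                    "frame": i,
                    "intensity": realized,
                    "sigma": max(config.gain * np.sqrt(max(n_events, 1.0)) / avg, 1e-9),
                    "tilt": phi_frames[i],
                }
            )
        if config.read_noise_sd > 0:
            frames[i] += noise_rng.normal(0.0, config.read_noise_sd, size=(rows, cols))
        frames[i] -= config.pedestal_truth

    clipped = [
        float(np.count_nonzero(frames[i] + config.pedestal_truth < 0)) / (rows * cols)
        for i in range(config.n_frames)
    ]
    table = pd.DataFrame.from_records(
        records, columns=["h", "k", "l", "frame", "intensity", "sigma", "tilt"]
    )
    truth = GroundTruth(
        reflection_table=table,
        true_gain=config.gain,
        true_B=config.decay_B,
        true_D50=float(np.log(2) / config.decay_B) if config.decay_B > 0 else np.inf,
        clipped_fractions=clipped,
        skipped_spots=skipped,
    )
    stack = FrameStack(
        pixels=frames,
        source_format="SYNTHETIC",
        per_frame_time=geom.exposure_time_s,
    )
    return stack, truth


def simulate_reflection_table(
    config: SimulationConfig,
    n_crystals: int = 1,
    noise_cv: float = 0.0,
    d_min: float | None = None,
    obs_per_frame: int | None = None,
) -> list[pd.DataFrame]:
    """Reflection tables whose frame means follow A_cryst * exp(-B x).

    Per crystal an amplitude A_cryst is drawn, and every frame carries
    ``obs_per_frame`` observations with mean A_cryst * exp(-B x_frame)
    and multiplicative Gaussian noise of coefficient of variation
    ``noise_cv``.  Miller indices cycle deterministically through the
    unique set so completeness grows with frame number; the tilt column
    ramps linearly with the rotation.
    """
    if n_crystals < 1:
        raise ValueError("n_crystals must be >= 1")
    geom = config.geometry
    if d_min is None:
        d_min = edge_resolution(geom)
    unique = sorted(generate_unique_set(config.cell, d_min, config.laue_group))
    if not unique:
        raise ValueError(f"no reflections at d >= {d_min} A for this cell")
    if obs_per_frame is None:
        obs_per_frame = max(1, round(2 * len(unique) / config.n_frames))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    ledger = exposure_ledger(geom, config.n_frames)
    dphi = delta_phi_per_frame(geom)
    tables = []
    for c in range(n_crystals):
        a_cryst = 100.0 * np.exp(rng.uniform(-0.5, 0.5))
        records = []
        cursor = 0
        for i in range(config.n_frames):
            x_i = ledger.cumulative_exposure[i]
            mean = a_cryst * np.exp(-config.decay_B * x_i)
            tilt = config.tilt_start_deg - dphi * i
            for _ in range(obs_per_frame):
                h, k, l = unique[cursor % len(unique)]
                cursor += 1
                if noise_cv > 0:
                    intensity = mean * (1.0 + noise_cv * rng.standard_normal())
                    sigma = mean * noise_cv
                else:
                    intensity, sigma = mean, max(mean * 1e-6, 1e-9)
                records.append(
                    {
                        "h": h,
                        "k": k,
                        "l": l,
                        "frame": i,
                        "intensity": intensity,
                        "sigma": sigma,
                        "tilt": tilt,
                    }
                )
        tables.append(
            pd.DataFrame.from_records(
                records, columns=["h", "k", "l", "frame", "intensity", "sigma", "tilt"]
            )
        )
    return tables
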