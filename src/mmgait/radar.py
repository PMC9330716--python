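"""FMCW radar waveform configuration and closed-form range/Doppler/angle equations.

The default configuration mirrors a TI IWR6843ISK-ODS short-range profile:
a 60.75 GHz start frequency, 1780.393 MHz valid sweep bandwidth, 3 TX x 4 RX
TDM-MIMO, 96 ADC samples per chirp and 288 chirps per 55 ms frame.  From the
bandwidth B and the ADC sampling window the usual FMCW identities follow:

    dR   = c / (2 B)                     (range resolution)
    Rmax = n_samples * dR                (max unambiguous range)
    S    = B / T_adc                     (chirp slope, T_adc = n_samples / Fs)
    d    = f_if * c / (2 S)              (beat frequency -> range)
    v    = w * lambda / (4 pi * Tc)      (chirp-pair phase -> radial velocity)
    theta= asin(w * lambda / (2 pi d))   (antenna-pair phase -> angle of arrival)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml

SPEED_OF_LIGHT = 2.99792458e8  # m/s


class RadarConfigError(ValueError):
    """Raised for physically inconsistent waveform parameters."""


@dataclass(frozen=True)
class RadarConfig:
    """FMCW waveform and antenna parameters (defaults: 60 GHz ODS profile)."""

    start_frequency: float = 60.75e9        # Hz
    center_frequency: float = 63.008e9      # Hz
    sweep_bandwidth: float = 1780.393e6     # Hz, valid (sampled) sweep
    n_tx: int = 3
    n_rx: int = 4
    n_samples_per_chirp: int = 96
    n_chirps_per_frame: int = 288
    sampling_rate: float = 2.950e6          # complex samples / s
    idle_time: float = 30e-6                # s, between chirps
    adc_start_time: float = 25e-6           # s, ramp start -> ADC start
    frame_period: float = 55e-3             # s
    range_threshold_db: float = 15.0        # CFAR threshold, range dimension
    doppler_threshold_db: float = 15.0      # CFAR threshold, Doppler dimension
    # Printed datasheet Doppler limits; the exact chirp ramp timing that yields
    # them is underdetermined, so they are carried as configured constants and
    # self-consistent values are derived from the timing below.
    configured_max_doppler: float = 4.450       # m/s
    configured_doppler_resolution: float = 0.093  # m/s

    def __post_init__(self) -> None:
        positive = (
            "start_frequency", "center_frequency", "sweep_bandwidth", "n_tx",
            "n_rx", "n_samples_per_chirp", "n_chirps_per_frame",
            "sampling_rate", "frame_period",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise RadarConfigError(f"{name} must be strictly positive")
        if self.center_frequency < self.start_frequency:
            raise RadarConfigError("center_frequency must be >= start_frequency")
        if self.n_chirps_per_frame % self.n_tx:
            raise RadarConfigError("n_chirps_per_frame must divide evenly over n_tx")

    # -- timing ----------------------------------------------------------
    @property
    def adc_sampling_time(self) -> float:
        """Duration of the sampled part of one chirp ramp (s)."""
        return self.n_samples_per_chirp / self.sampling_rate

    @property
    def chirp_repetition_interval(self) -> float:
        """Chirp-to-chirp interval: idle + ADC start + sampled ramp (s)."""
        return self.idle_time + self.adc_start_time + self.adc_sampling_time

    @property
    def n_virtual_antennas(self) -> int:
        return self.n_tx * self.n_rx

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RadarConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def replace(self, **kwargs) -> "RadarConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DerivedRadarQuantities:
    """Quantities derived from a :class:`RadarConfig` by the FMCW identities."""

    wavelength: float          # m, at center frequency
    chirp_slope: float         # Hz/s over the sampled ramp
    range_resolution: float    # m
    max_range: float           # m
    doppler_resolution: float  # m/s, from the effective TDM chirp interval
    max_doppler: float         # m/s, one-sided unambiguous limit
    n_doppler_bins: int        # chirps per TX


def derive_quantities(config: RadarConfig) -> DerivedRadarQuantities:
    """Derive resolutions and unambiguous limits from the waveform parameters.

    TDM-MIMO over ``n_tx`` transmitters stretches the effective Doppler
    sampling interval to ``n_tx * chirp_repetition_interval``.
    """
    b = config.sweep_bandwidth
    wavelength = SPEED_OF_LIGHT / config.center_frequency
    slope = b / config.adc_sampling_time
    d_r = SPEED_OF_LIGHT / (2.0 * b)
    r_max = config.n_samples_per_chirp * d_r
    n_doppler = config.n_chirps_per_frame // config.n_tx
    t_eff = config.n_tx * config.chirp_repetition_interval
    d_max = wavelength / (4.0 * t_eff)
    d_res = 2.0 * d_max / n_doppler
    return DerivedRadarQuantities(
        wavelength=wavelength,
        chirp_slope=slope,
        range_resolution=d_r,
        max_range=r_max,
        doppler_resolution=d_res,
        max_doppler=d_max,
        n_doppler_bins=n_doppler,
    )


def if_frequency_to_range(f_if: float, config: RadarConfig) -> float:
    """Map a beat (IF) frequency to target range: ``d = f_if c / (2 S)``."""
    f_if = np.asarray(f_if, dtype=float)
    if np.any(f_if < 0):
        raise ValueError("IF frequency must be non-negative")
    # complex (I/Q) sampling: beat frequencies are unambiguous up to Fs
    if np.any(f_if > config.sampling_rate):
        warnings.warn(
            "IF frequency exceeds the complex sampling rate; the returned "
            "range is the un-aliased extrapolation", RuntimeWarning,
        )
    slope = config.sweep_bandwidth / config.adc_sampling_time
    out = f_if * SPEED_OF_LIGHT / (2.0 * slope)
    return float(out) if out.ndim == 0 else out


def range_to_if_frequency(d: float, config: RadarConfig) -> float:
    """Inverse of :func:`if_frequency_to_range` (``f_if = 2 S d / c``)."""
    slope = config.sweep_bandwidth / config.adc_sampling_time
    return 2.0 * slope * np.asarray(d, dtype=float) / SPEED_OF_LIGHT


def phase_to_velocity(phase_diff: float, chirp_interval: float,
                      config: RadarConfig) -> float:
    """Chirp-to-chirp phase difference to radial velocity.

    ``v = w lambda / (4 pi Tc)`` with ``w`` in (-pi, pi] and ``Tc`` the
    (effective) Doppler sampling interval.
    """
    if chirp_interval <= 0:
        raise ValueError("chirp_interval must be positive")
    wavelength = SPEED_OF_LIGHT / config.center_frequency
    return np.asarray(phase_diff, dtype=float) * wavelength / (4.0 * math.pi * chirp_interval)


def phase_to_aoa(phase_diff: float, antenna_spacing: float,
                 config: RadarConfig) -> float:
    """Inter-antenna phase difference to angle of arrival, in degrees.

    ``theta = asin(w lambda / (2 pi d))``; raises if the argument falls
    outside [-1, 1] (spatial aliasing).
    """
    if antenna_spacing <= 0:
        raise ValueError("antenna_spacing must be positive")
    wavelength = SPEED_OF_LIGHT / config.center_frequency
    arg = np.asarray(phase_diff, dtype=float) * wavelength / (2.0 * math.pi * antenna_spacing)
    if np.any(np.abs(arg) > 1.0 + 1e-12):
        raise ValueError("phase difference outside the unambiguous angle range (aliased)")
    out = np.degrees(np.arcsin(np.clip(arg, -1.0, 1.0)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RadarMount:
    """Rigid transform between the radar antenna frame and the world frame.

    World frame: x lateral, y depth away from the radar, z vertical up, the
    floor at z = 0.  The sensor sits at ``height`` above the floor, pitched
    down by ``tilt_deg`` about the world x axis (a wall/tripod mount looking
    slightly at the floor).  Radar frame: x lateral, y along boresight,
    z up in the antenna plane.
    """

    height: float = 2.0
    tilt_deg: float = 15.0

    @property
    def position(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.height])

    @property
    def rotation(self) -> np.ndarray:
        """Rotation matrix mapping radar-frame vectors to world-frame."""
        t = math.radians(self.tilt_deg)
        # pitch down: boresight +y_radar maps to (0, cos t, -sin t) in world
        return np.array([
            [1.0, 0.0, 0.0],
            [0.0, math.cos(t), math.sin(t)],
            [0.0, -math.sin(t), math.cos(t)],
        ]).T

    def radar_to_world(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.position
        return out[0] if np.asarray(points).ndim == 1 else out

    def world_to_radar(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.position) @ self.rotation
        return out[0] if np.asarray(points).ndim == 1 else out

    def spherical_to_world(self, rng: np.ndarray, azimuth_deg: np.ndarray,
                           elevation_deg: np.ndarray) -> np.ndarray:
        """(range, bearing, elevation) in the radar frame to world xyz.

        Bearing is positive to the radar's left; elevation positive above
        boresight.
        """
        az = np.radians(np.asarray(azimuth_deg, dtype=float))
        el = np.radians(np.asarray(elevation_deg, dtype=float))
        r = np.asarray(rng, dtype=float)
        x = -r * np.cos(el) * np.sin(az)
        y = r * np.cos(el) * np.cos(az)
        z = r * np.sin(el)
        return self.radar_to_world(np.stack([x, y, z], axis=-1))

    def world_to_spherical(self, points: np.ndarray):
        """World xyz to (range, bearing deg, elevation deg)."""
        p = self.world_to_radar(points)
        p = np.atleast_2d(p)
        r = np.linalg.norm(p, axis=-1)
        az = np.degrees(np.arctan2(-p[..., 0], p[..., 1]))
        el = np.degrees(np.arcsin(np.clip(p[..., 2] / np.maximum(r, 1e-12), -1, 1)))
        if np.asarray(points).ndim == 1:
            return float(r[0]), float(az[0]), float(el[0])
        return r, az, el
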