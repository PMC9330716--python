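"""Per-track micro-Doppler spectrograms from tracked point clouds.

Each tracked point deposits its intensity — compensated for the 1/r^2 range
attenuation — into the Doppler-velocity bin of its frame column.  Sliding
windows over the resulting velocity x time matrix give the classifier
inputs; every spectrogram is normalized so its maximum is one, which makes
the downstream classifier invariant to absolute reflected power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import zoom

from .pointcloud import PointCloudFrame
from .radar import RadarConfig, derive_quantities


@dataclass
class MicroDopplerSpectrogram:
    """Velocity-bin x time intensity matrix for one track.

    ``values`` spans ``velocity_axis`` (m/s, +-Dmax) by ``time_axis`` (s);
    after normalization all values lie in [0, 1] with max 1 for nonempty
    input.
    """

    values: np.ndarray
    velocity_axis: np.ndarray
    time_axis: np.ndarray
    track_id: int = -1
    label: str | None = None


def compensate_intensity(intensity: np.ndarray, ranges: np.ndarray,
                         r_ref: float = 1.0) -> np.ndarray:
    """Undo the 1/r^2 range attenuation: multiply by (r / r_ref)^2."""
    ranges = np.asarray(ranges, dtype=float)
    if np.any(ranges <= 0):
        raise ValueError("ranges must be positive")
    return np.asarray(intensity, dtype=float) * (ranges / r_ref) ** 2


def normalize_to_one(values: np.ndarray) -> np.ndarray:
    """Divide by the matrix maximum; an all-zero matrix is returned unchanged."""
    m = float(np.max(values)) if values.size else 0.0
    return values / m if m > 0 else values


def compensate_and_normalize(values: np.ndarray,
                             deposit_ranges: np.ndarray | None = None,
                             deposit_bins: tuple | None = None,
                             r_ref: float = 1.0) -> np.ndarray:
    """Range-compensate deposits (when given) and normalize the matrix to one.

    When ``deposit_ranges``/``deposit_bins`` are omitted the matrix is
    assumed already compensated and only the unit normalization is applied.
    """
    if deposit_ranges is not None and deposit_bins is not None:
        out = np.zeros_like(np.asarray(values, dtype=float))
        w = compensate_intensity(np.ones_like(deposit_ranges), deposit_ranges,
                                 r_ref)
        np.add.at(out, deposit_bins, w * values[deposit_bins])
        return normalize_to_one(out)
    return normalize_to_one(np.asarray(values, dtype=float))


def accumulate_spectrogram(frames: list[PointCloudFrame], track_id: int,
                           config: RadarConfig, window: float = 2.0,
                           stride: float | None = None, r_ref: float = 1.0,
                           compensate: bool = True,
                           label: str | None = None
                           ) -> list[MicroDopplerSpectrogram]:
    """Sliding-window micro-Doppler spectrograms for one track.

    ``window`` (s) must cover at least one frame period; ``stride`` defaults
    to one frame.  Raises if the track id never occurs in the frames.
    """
    if not frames:
        return []
    frame_period = config.frame_period
    if window < frame_period:
        raise ValueError("window must be at least one frame period")
    dq = derive_quantities(config)
    n_bins = dq.n_doppler_bins
    vel_axis = (np.arange(n_bins) - n_bins // 2) * dq.doppler_resolution

    present = any(np.any(f.track_id == track_id) for f in frames)
    if not present:
        raise ValueError(f"track id {track_id} not present in the frames")

    n_t = len(frames)
    full = np.zeros((n_bins, n_t))
    times = np.array([f.timestamp for f in frames])
    for j, f in enumerate(frames):
        sel = f.track_id == track_id
        if not np.any(sel):
            continue
        dop = f.doppler[sel]
        inten = f.intensity[sel]
        if compensate:
            rr = f.rng[sel]
            rr = np.where(np.isfinite(rr), rr, 1.0)
            inten = compensate_intensity(inten, np.maximum(rr, 0.3), r_ref)
        bins = np.clip(np.round(dop / dq.doppler_resolution).astype(int)
                       + n_bins // 2, 0, n_bins - 1)
        np.add.at(full[:, j], bins, inten)

    w_frames = max(int(round(window / frame_period)), 1)
    s_frames = max(int(round((stride or frame_period) / frame_period)), 1)
    out = []
    for start in range(0, n_t - w_frames + 1, s_frames):
        vals = normalize_to_one(full[:, start:start + w_frames].copy())
        out.append(MicroDopplerSpectrogram(
            values=vals, velocity_axis=vel_axis,
            time_axis=times[start:start + w_frames], track_id=track_id,
            label=label))
    return out


def resample_spectrogram(spec: MicroDopplerSpectrogram,
                         shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Resize to the classifier input shape, re-normalized to max one."""
    v = spec.values
    if v.size == 0:
        return np.zeros(shape)
    factors = (shape[0] / v.shape[0], shape[1] / v.shape[1])
    out = zoom(v, factors, order=1, mode="nearest", grid_mode=True)
    return normalize_to_one(np.clip(out[:shape[0], :shape[1]], 0.0, None))


def log_compress(values: np.ndarray, alpha: float = 100.0) -> np.ndarray:
    """Logarithmic dynamic-range compression, preserving the [0, 1] scale.

    The torso's bulk-Doppler line carries far more power than the limb
    micro-Doppler wings; compressing as log(1 + alpha v) / log(1 + alpha)
    brings the wings into the classifier's working range.
    """
    return np.log1p(alpha * np.asarray(values, dtype=float)) / np.log1p(alpha)


def save_spectrogram_png(spec: MicroDopplerSpectrogram, path) -> None:
    """Export a quick-look image (velocity vs time)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    extent = [spec.time_axis[0], spec.time_axis[-1],
              spec.velocity_axis[0], spec.velocity_axis[-1]]
    ax.imshow(spec.values, aspect="auto", origin="lower", extent=extent,
              cmap="jet")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("velocity (m/s)")
    if spec.label:
        ax.set_title(spec.label)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
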