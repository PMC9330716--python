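"""Echo-level FMCW forward model: scatterers -> deramped IF radar cubes.

One frame's cube holds complex IF samples indexed
(virtual antenna, chirp-within-TX, fast-time sample).  The virtual array is
modelled as a uniform planar aperture: ``n_rx`` half-wavelength elements
along the radar x axis (azimuth) by ``n_tx`` along z (elevation), filled by
TDM-MIMO, so TX slot ``e`` fires at time offset ``e * Tc`` within each chirp
group.

Per scatterer i at range r, approaching radial velocity v, direction cosines
(u_x, u_z), the deramped IF contribution at fast time t and slow time t_k is

    a_i exp(j [2 pi f_b t + 4 pi r / lambda - 4 pi v t_k / lambda
               + 2 pi d (a u_x + e u_z) / lambda])

with beat frequency f_b = 2 S r / c and amplitude a_i = reflectivity / r^2
(the "range effect" the spectrogram stage later compensates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pointcloud import ScattererSet
from .radar import (SPEED_OF_LIGHT, RadarConfig, RadarMount, derive_quantities)


@dataclass
class RadarCube:
    """Complex IF samples of one frame: (n_virtual, n_chirps_per_tx, n_samples)."""

    timestamp: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (antenna, chirp, sample)")


def save_cubes(cubes: list[RadarCube], path) -> None:
    """Persist a frame sequence of IF cubes to an HDF5 container."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("timestamps",
                         data=np.array([c.timestamp for c in cubes]))
        f.create_dataset("cubes", data=np.stack([c.data for c in cubes]),
                         compression="gzip")


def load_cubes(path) -> list[RadarCube]:
    import h5py
    with h5py.File(path, "r") as f:
        ts = f["timestamps"][:]
        data = f["cubes"][:]
    return [RadarCube(timestamp=float(t), data=d) for t, d in zip(ts, data)]


def virtual_antenna_indices(config: RadarConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(azimuth index, elevation index, tx slot) per virtual channel.

    Virtual channel v = e * n_rx + a: RX index a spans azimuth, TX index e
    spans elevation and sets the TDM firing slot.
    """
    v = np.arange(config.n_virtual_antennas)
    a = v % config.n_rx
    e = v // config.n_rx
    return a, e, e


def synth_radar_cube(scatterers: ScattererSet, config: RadarConfig,
                     noise_std: float = 0.0,
                     seed: int | np.random.Generator = 0,
                     mount: RadarMount | None = None,
                     drop_out_of_range: bool = True) -> list[RadarCube]:
    """Simulate the deramped echo of every frame of a scatterer set.

    Scatterers beyond the unambiguous range are dropped (with a warning) or,
    if ``drop_out_of_range`` is false, kept and left to alias.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mount = mount or RadarMount()
    dq = derive_quantities(config)
    lam = dq.wavelength
    slope = dq.chirp_slope
    n_s = config.n_samples_per_chirp
    n_d = dq.n_doppler_bins
    n_v = config.n_virtual_antennas
    tcr = config.chirp_repetition_interval
    spacing = lam / 2.0
    az_idx, el_idx, tx_slot = virtual_antenna_indices(config)

    t_fast = np.arange(n_s) / config.sampling_rate              # (n_s,)
    chirp_of_tx = np.arange(n_d)                                # (n_d,)

    cubes: list[RadarCube] = []
    warned = False
    for f in range(scatterers.n_frames):
        pos_r = mount.world_to_radar(scatterers.positions[f])
        rel = scatterers.positions[f] - mount.position
        r = np.linalg.norm(rel, axis=1)
        v_r = -np.sum(rel / np.maximum(r, 1e-12)[:, None]
                      * scatterers.velocities[f], axis=1)
        keep = np.ones(len(r), bool)
        if np.any(r > dq.max_range):
            if not warned:
                warnings.warn("scatterer(s) beyond the unambiguous range",
                              RuntimeWarning)
                warned = True
            if drop_out_of_range:
                keep = r <= dq.max_range
        r, v_r = r[keep], v_r[keep]
        pos_r = np.atleast_2d(pos_r)[keep]
        refl = scatterers.reflectivity[keep]
        u_x = pos_r[:, 0] / np.maximum(r, 1e-12)
        u_z = pos_r[:, 2] / np.maximum(r, 1e-12)

        amp = refl / np.maximum(r, 0.3) ** 2                    # (n_i,)
        f_b = 2.0 * slope * r / SPEED_OF_LIGHT                  # (n_i,)
        # slow time of chirp k on TX slot e: (k * n_tx + e) * tcr
        t_slow = (chirp_of_tx[None, :] * config.n_tx
                  + tx_slot[:, None]) * tcr                     # (n_v, n_d)
        # phase pieces, broadcast to (n_i, n_v, n_d, n_s)
        ph_fast = 2.0 * np.pi * f_b[:, None] * t_fast[None, :]  # (n_i, n_s)
        ph_const = 4.0 * np.pi * r / lam                        # (n_i,)
        ph_dopp = (-4.0 * np.pi / lam) * v_r[:, None, None] * t_slow[None]  # (n_i, n_v, n_d)
        ph_space = (2.0 * np.pi * spacing / lam) * (
            az_idx[None, :] * u_x[:, None] + el_idx[None, :] * u_z[:, None])  # (n_i, n_v)
        phase = (ph_dopp[..., None] + ph_space[:, :, None, None]
                 + ph_fast[:, None, None, :] + ph_const[:, None, None, None])
        cube = np.sum(amp[:, None, None, None] * np.exp(1j * phase), axis=0) \
            if len(r) else np.zeros((n_v, n_d, n_s), np.complex128)
        if noise_std > 0:
            cube = cube + (rng.normal(0, noise_std / np.sqrt(2), cube.shape)
                           + 1j * rng.normal(0, noise_std / np.sqrt(2), cube.shape))
        cubes.append(RadarCube(timestamp=float(scatterers.timestamps[f]),
                               data=cube))
    return cubes
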