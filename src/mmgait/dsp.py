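"""Radar cube -> detected, clustered, tracked 5D point clouds.

The five processing steps: windowed range FFT, Doppler FFT (per TX
de-multiplexed), moving-target indication, 2-D cell-averaging CFAR, FFT
angle estimation over the virtual aperture, then DBSCAN clustering and
constant-velocity Kalman tracking of cluster centroids.  Everything in this
module is deterministic given its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann
from sklearn.cluster import DBSCAN

from .echo import RadarCube, virtual_antenna_indices
from .pointcloud import PointCloudFrame
from .radar import RadarConfig, RadarMount, derive_quantities


@dataclass
class RangeDopplerMap:
    """Per-antenna complex range-Doppler spectra of one frame.

    ``data``: (n_virtual, n_range_bins, n_doppler_bins), Doppler axis
    fft-shifted.  ``range_axis`` (m) and ``velocity_axis`` (m/s, approaching
    positive) calibrate the bins.
    """

    timestamp: float
    data: np.ndarray
    range_axis: np.ndarray
    velocity_axis: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        """Non-coherent sum of per-antenna power, (n_range, n_doppler)."""
        return np.sum(np.abs(self.data) ** 2, axis=0)


def range_doppler_map(cube: RadarCube, config: RadarConfig) -> RangeDopplerMap:
    """Hann-windowed FFT over fast time, then over chirps (slow time).

    The Doppler axis uses the effective TDM chirp interval (n_tx chirps
    between same-TX revisits); approaching targets land on positive
    velocities.
    """
    dq = derive_quantities(config)
    n_v, n_d, n_s = cube.data.shape
    if n_v != config.n_virtual_antennas or n_s != config.n_samples_per_chirp \
            or n_d != dq.n_doppler_bins:
        raise ValueError(
            f"cube dims {cube.data.shape} do not match the configuration "
            f"({config.n_virtual_antennas}, {dq.n_doppler_bins}, "
            f"{config.n_samples_per_chirp})")
    w_fast = hann(n_s, sym=False)
    w_slow = hann(n_d, sym=False)
    x = cube.data * w_fast[None, None, :]
    rfft = np.fft.fft(x, axis=2)                       # range spectrum
    rfft = rfft * w_slow[None, :, None]
    dfft = np.fft.fftshift(np.fft.fft(rfft, axis=1), axes=1)
    data = np.transpose(dfft, (0, 2, 1))               # (ant, range, doppler)
    range_axis = np.arange(n_s) * dq.range_resolution
    # beat phase advances by -4 pi v Teff / lambda per revisit: approaching
    # (v > 0) targets appear at negative DFT frequencies, so flip the axis
    dopp_bins = np.fft.fftshift(np.fft.fftfreq(n_d)) * n_d
    velocity_axis = -dopp_bins * dq.doppler_resolution
    return RangeDopplerMap(timestamp=cube.timestamp, data=data,
                           range_axis=range_axis, velocity_axis=velocity_axis)


def mti_filter(maps: list[RangeDopplerMap], mode: str = "wide",
               guard_bins: int = 1) -> list[RangeDopplerMap]:
    """Suppress static clutter by nulling zero-Doppler content.

    ``mode='dc'`` nulls only the zero-velocity bin (subtracting each range
    bin's slow-time mean before the Doppler FFT, for unwindowed data);
    ``mode='wide'`` (default) also nulls ``guard_bins`` bins either side,
    which catches the Hann-window leakage of static returns.
    """
    if mode not in ("dc", "wide"):
        raise ValueError("mode must be 'dc' or 'wide'")
    out = []
    for m in maps:
        dc = int(np.argmin(np.abs(m.velocity_axis)))
        lo, hi = (dc, dc + 1) if mode == "dc" else (dc - guard_bins,
                                                    dc + guard_bins + 1)
        data = m.data.copy()
        data[:, :, max(lo, 0):hi] = 0.0
        out.append(RangeDopplerMap(timestamp=m.timestamp, data=data,
                                   range_axis=m.range_axis,
                                   velocity_axis=m.velocity_axis))
    return out


def ca_cfar_pfa(threshold_db: float, n_training: int) -> float:
    """Closed-form false-alarm probability of cell-averaging CFAR.

    For exponentially distributed noise power and a threshold of T (linear)
    times the mean of N training cells, Pfa = (1 + T/N)^-N.
    """
    t = 10.0 ** (threshold_db / 10.0)
    return float((1.0 + t / n_training) ** (-n_training))


@dataclass(frozen=True)
class Detection:
    range_bin: int
    doppler_bin: int
    range: float
    velocity: float
    intensity: float


def cfar_detect(rd: RangeDopplerMap, config: RadarConfig,
                threshold_db: float | None = None,
                guard: int = 2, train: int = 4) -> list[Detection]:
    """2-D cell-averaging CFAR on the non-coherent power map.

    A cell passes when its power exceeds the mean of the surrounding
    training ring (``train`` cells beyond ``guard`` guard cells per side in
    each dimension) by ``threshold_db`` (default: the configured range
    detection threshold).  Detections are invariant to global scaling of the
    map by construction.
    """
    if threshold_db is None:
        threshold_db = max(config.range_threshold_db, config.doppler_threshold_db)
    power = rd.magnitude
    w = 2 * (guard + train) + 1
    if min(power.shape) < w:
        raise ValueError(f"map {power.shape} smaller than the CFAR window {w}")
    from scipy.ndimage import uniform_filter
    big = uniform_filter(power, size=w, mode="wrap") * w * w
    small_w = 2 * guard + 1
    small = uniform_filter(power, size=small_w, mode="wrap") * small_w * small_w
    n_train = w * w - small_w * small_w
    noise = (big - small) / n_train
    thresh = 10.0 ** (threshold_db / 10.0)
    hits = power > thresh * np.maximum(noise, 1e-300)
    out = []
    for rb, db in np.argwhere(hits):
        out.append(Detection(range_bin=int(rb), doppler_bin=int(db),
                             range=float(rd.range_axis[rb]),
                             velocity=float(rd.velocity_axis[db]),
                             intensity=float(power[rb, db])))
    return out


def estimate_angles(rd: RangeDopplerMap, detections: list[Detection],
                    config: RadarConfig, mount: RadarMount | None = None,
                    n_fft: int = 64) -> PointCloudFrame:
    """Zero-padded FFT angle estimation over the planar virtual aperture.

    Per detection, the 12-channel snapshot is TDM-Doppler-compensated,
    beamformed in azimuth (n_rx elements) and elevation (n_tx elements),
    and the (range, azimuth, elevation) triple is mapped to world xyz
    through the radar mount transform.
    """
    if config.n_rx < 2:
        raise ValueError("angle estimation needs >= 2 antennas per axis")
    mount = mount or RadarMount()
    dq = derive_quantities(config)
    az_idx, el_idx, tx_slot = virtual_antenna_indices(config)
    lam = dq.wavelength
    tcr = config.chirp_repetition_interval
    xyz, dops, intens, rngs = [], [], [], []
    ux_grid = 2.0 * np.fft.fftshift(np.fft.fftfreq(n_fft))   # for d = lambda/2
    for det in detections:
        snap = rd.data[:, det.range_bin, det.doppler_bin]
        # undo the per-TX-slot Doppler phase progression
        comp = np.exp(1j * 4.0 * np.pi * det.velocity * tx_slot * tcr / lam)
        snap = (snap * comp).reshape(config.n_tx, config.n_rx)
        az_spec = np.fft.fftshift(np.fft.fft(snap, n=n_fft, axis=1), axes=1)
        # azimuth: peak over the aperture FFT, non-coherent across TX rows
        az_prof = np.sum(np.abs(az_spec) ** 2, axis=0)
        qa = int(np.argmax(az_prof))
        u_x = ux_grid[qa]
        # elevation: beamform the azimuth-aligned snapshot across TX rows
        steer = np.exp(-1j * np.pi * np.arange(config.n_rx) * u_x)
        rows = snap @ steer
        el_fft = np.fft.fftshift(np.fft.fft(rows, n=n_fft))
        qe = int(np.argmax(np.abs(el_fft) ** 2))
        u_z = ux_grid[qe]
        uu = u_x ** 2 + u_z ** 2
        if uu >= 1.0:
            nrm = np.sqrt(uu) / 0.999
            u_x, u_z = u_x / nrm, u_z / nrm
        u_y = np.sqrt(max(1.0 - u_x ** 2 - u_z ** 2, 0.0))
        p_radar = det.range * np.array([u_x, u_y, u_z])
        p_world = mount.radar_to_world(p_radar)
        xyz.append(p_world)
        dops.append(det.velocity)
        intens.append(det.intensity)
        rngs.append(det.range)
    if not xyz:
        return PointCloudFrame(timestamp=rd.timestamp,
                               xyz=np.zeros((0, 3)), doppler=np.zeros(0),
                               intensity=np.zeros(0), rng=np.zeros(0))
    return PointCloudFrame(timestamp=rd.timestamp, xyz=np.asarray(xyz),
                           doppler=np.asarray(dops),
                           intensity=np.asarray(intens), rng=np.asarray(rngs))


def cluster_points(frame: PointCloudFrame, eps: float = 0.3,
                   min_points: int = 5) -> PointCloudFrame:
    """DBSCAN over (x, y, z); noise points keep cluster_id -1 (none)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    if len(frame) == 0:
        return frame
    labels = DBSCAN(eps=eps, min_samples=min_points).fit_predict(frame.xyz)
    out = frame.subset(np.ones(len(frame), bool))
    out.cluster_id = labels.astype(int)
    return out


# ---------------------------------------------------------------------------
# constant-velocity Kalman tracking of cluster centroids
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """One tracked subject: position+velocity state with covariance."""

    track_id: int
    state: np.ndarray                  # (6,) x y z vx vy vz
    covariance: np.ndarray             # (6, 6)
    age: int = 0
    missed: int = 0
    hits: int = 0
    confirmed: bool = False
    last_timestamp: float = 0.0

    @property
    def position(self) -> np.ndarray:
        return self.state[:3]

    @property
    def velocity(self) -> np.ndarray:
        return self.state[3:]


def _cv_matrices(dt: float, q_accel: float, r_meas: float):
    f = np.eye(6)
    f[:3, 3:] = dt * np.eye(3)
    g = np.concatenate([0.5 * dt * dt * np.eye(3), dt * np.eye(3)])
    q = q_accel ** 2 * (g @ g.T)
    h = np.zeros((3, 6))
    h[:, :3] = np.eye(3)
    r = r_meas ** 2 * np.eye(3)
    return f, q, h, r


class CentroidTracker:
    """Nearest-centroid gated association with CV Kalman filtering.

    Tracks are confirmed after ``confirm_hits`` consecutive hits and dropped
    after ``max_missed`` consecutive misses.
    """

    def __init__(self, gate: float = 0.8, confirm_hits: int = 3,
                 max_missed: int = 5, q_accel: float = 2.0,
                 r_meas: float = 0.12):
        self.gate = gate
        self.confirm_hits = confirm_hits
        self.max_missed = max_missed
        self.q_accel = q_accel
        self.r_meas = r_meas
        self.tracks: list[Track] = []
        self._next_id = 0

    def step(self, timestamp: float, centroids: np.ndarray) -> dict[int, int]:
        """Advance one frame; returns {centroid row -> track_id}."""
        for tr in self.tracks:
            dt = timestamp - tr.last_timestamp
            if dt > 0:
                f, q, _, _ = _cv_matrices(dt, self.q_accel, self.r_meas)
                tr.state = f @ tr.state
                tr.covariance = f @ tr.covariance @ f.T + q
                tr.last_timestamp = timestamp
            tr.age += 1
        assignment: dict[int, int] = {}
        unused = list(range(len(centroids)))
        matched: set[int] = set()
        # greedy nearest association, confirmed/older tracks first
        order = sorted(range(len(self.tracks)),
                       key=lambda i: (not self.tracks[i].confirmed,
                                      -self.tracks[i].age))
        for ti in order:
            tr = self.tracks[ti]
            if not unused:
                break
            d = np.linalg.norm(centroids[unused] - tr.position, axis=1)
            j = int(np.argmin(d))
            if d[j] <= self.gate:
                ci = unused.pop(j)
                z = centroids[ci]
                _, _, h, r = _cv_matrices(1.0, self.q_accel, self.r_meas)
                s = h @ tr.covariance @ h.T + r
                k = tr.covariance @ h.T @ np.linalg.inv(s)
                tr.state = tr.state + k @ (z - h @ tr.state)
                tr.covariance = (np.eye(6) - k @ h) @ tr.covariance
                # keep covariance symmetric against round-off
                tr.covariance = 0.5 * (tr.covariance + tr.covariance.T)
                tr.hits += 1
                tr.missed = 0
                if tr.hits >= self.confirm_hits:
                    tr.confirmed = True
                assignment[ci] = tr.track_id
                matched.add(ti)
        for ti, tr in enumerate(self.tracks):
            if ti not in matched:
                tr.missed += 1
                if not tr.confirmed:
                    tr.hits = 0          # confirmation needs consecutive hits
        self.tracks = [t for t in self.tracks if t.missed <= self.max_missed]
        # spawn tentative tracks on leftover centroids
        for ci in unused:
            p0 = np.zeros(6)
            p0[:3] = centroids[ci]
            cov = np.diag([0.25, 0.25, 0.25, 4.0, 4.0, 4.0])
            self.tracks.append(Track(track_id=self._next_id, state=p0,
                                     covariance=cov, age=1, hits=1,
                                     last_timestamp=timestamp))
            assignment[ci] = self._next_id
            self._next_id += 1
        return assignment


def track_subjects(frames: list[PointCloudFrame], gate: float = 0.8,
                   confirm_hits: int = 3, max_missed: int = 5
                   ) -> tuple[list[PointCloudFrame], list[Track]]:
    """Track clustered frames; every point inherits its cluster's track id.

    Frames must be chronological.  Returns the frames (track_id filled in)
    and the final track list.
    """
    ts = [f.timestamp for f in frames]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("frame timestamps must be strictly increasing")
    tracker = CentroidTracker(gate=gate, confirm_hits=confirm_hits,
                              max_missed=max_missed)
    out = []
    for frame in frames:
        labels = np.unique(frame.cluster_id[frame.cluster_id >= 0])
        centroids = np.array([frame.xyz[frame.cluster_id == c].mean(axis=0)
                              for c in labels]).reshape(-1, 3)
        assign = tracker.step(frame.timestamp, centroids)
        states = {t.track_id: t.state.copy() for t in tracker.tracks}
        track_id = np.full(len(frame), -1, dtype=int)
        track_state = np.full((len(frame), 6), np.nan)
        for row, cl in enumerate(labels):
            if row in assign:
                sel = frame.cluster_id == cl
                track_id[sel] = assign[row]
                track_state[sel] = states[assign[row]]
        new = frame.subset(np.ones(len(frame), bool))
        new.track_id = track_id
        new.track_state = track_state
        out.append(new)
    return out, tracker.tracks


def process_cubes(cubes: list[RadarCube], config: RadarConfig,
                  mount: RadarMount | None = None, mti_mode: str = "wide",
                  threshold_db: float | None = None, eps: float = 0.3,
                  min_points: int = 5, gate: float = 0.8
                  ) -> tuple[list[PointCloudFrame], list[Track]]:
    """Full chain: cubes -> RD maps -> MTI -> CFAR -> angles -> DBSCAN -> tracks."""
    mount = mount or RadarMount()
    maps = mti_filter([range_doppler_map(c, config) for c in cubes],
                      mode=mti_mode)
    frames = []
    for rd in maps:
        dets = cfar_detect(rd, config, threshold_db=threshold_db)
        frame = estimate_angles(rd, dets, config, mount=mount)
        frames.append(cluster_points(frame, eps=eps, min_points=min_points))
    return track_subjects(frames, gate=gate)
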