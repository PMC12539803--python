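"""Tongue-marker kinematics: direction extraction, categorical labels, lick metrics.

All positions are in millimetres in a cranial coordinate frame with the origin
at the posterior nasal spine. Axis convention used throughout the package:

* ``x`` — posterior (−) / anterior (+)
* ``y`` — left (−) / right (+)
* ``z`` — inferior (−) / superior (+)

Direction of movement over a short interval is summarised by the 3D angle

    theta = atan2(||v1 × v2||, v1 · v2)

between the marker position vectors ``v1`` (interval start) and ``v2``
(interval end), and by the displacement ``delta = v2 − v1`` whose component
signs define the eight direction octants (AntSupL, …, PostInfR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "MarkerTrajectory",
    "DirectionSample",
    "OCTANTS",
    "smooth_markers",
    "theta_3d",
    "octant_label",
    "lr_angle_and_bin",
    "yaw_pitch",
    "direction_sample",
    "tile_direction_samples",
    "lick_summaries",
    "balance_direction_samples",
    "kinematic_comparison",
]

#: The eight direction categories from the component signs of the displacement.
OCTANTS = (
    "AntSupL", "AntSupR", "AntInfL", "AntInfR",
    "PostSupL", "PostSupR", "PostInfL", "PostInfR",
)

#: Half-open 10° left-right bins covering [−30°, 30°).
LR_BIN_EDGES = np.arange(-30.0, 40.0, 10.0)


@dataclass(frozen=True)
class MarkerTrajectory:
    """A single marker sampled on a uniform time grid.

    Parameters
    ----------
    time : (N,) array, seconds, strictly increasing, uniform grid.
    position : (N, 3) array, mm, cranial frame.
    """

    time: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.position, dtype=float)
        if t.ndim != 1 or p.ndim != 2 or p.shape != (t.size, 3):
            raise ValueError("time must be (N,), position must be (N, 3)")
        dt = np.diff(t)
        if t.size >= 2 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time must be strictly increasing and uniformly sampled")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "position", p)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        if self.time.size < 2:
            raise ValueError("need at least two samples to define a rate")
        return 1.0 / (self.time[1] - self.time[0])

    def at(self, t: float) -> np.ndarray:
        """Position at the grid sample nearest to time ``t`` (within half a step)."""
        i = int(round((t - self.time[0]) * self.fs))
        if i < 0 or i >= self.time.size:
            raise ValueError(f"time {t} s outside trajectory")
        return self.position[i]


@dataclass(frozen=True)
class DirectionSample:
    """Direction of marker motion over one short interval."""

    t1: float
    t2: float
    v1: np.ndarray
    v2: np.ndarray
    delta: np.ndarray
    theta: float
    u: np.ndarray | None
    octant: str | None
    lr_angle: float
    lr_bin: int | None
    yaw: float
    pitch: float


def smooth_markers(raw: MarkerTrajectory, cutoff_hz: float = 30.0, order: int = 4) -> MarkerTrajectory:
    """Zero-phase low-pass Butterworth filter of marker positions.

    A 30 Hz cutoff at the 200 Hz acquisition rate removes tracking jitter
    while passing tongue-movement frequencies (< ~10 Hz) essentially
    unchanged. Filtering is forward-backward (``filtfilt``), so no phase lag
    is introduced.
    """
    fs = raw.fs
    if fs <= 2.0 * cutoff_hz:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the cutoff {cutoff_hz} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    smoothed = signal.sosfiltfilt(sos, raw.position, axis=0)
    return MarkerTrajectory(raw.time, smoothed)


def theta_3d(v1: np.ndarray, v2: np.ndarray) -> float:
    """3D angle between position vectors, degrees in [0, 180].

    theta = atan2(||v1 × v2||, v1 · v2); the two-argument arctangent keeps
    obtuse angles in the upper quadrant.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("theta undefined for zero-norm position vector")
    cross = np.linalg.norm(np.cross(v1, v2))
    dot = float(np.dot(v1, v2))
    return float(np.degrees(np.arctan2(cross, dot)))


def octant_label(delta: np.ndarray) -> str:
    """Direction octant from the component signs of a displacement.

    Zero components are deterministically assigned to the positive side
    (anterior / right / superior), so labelling partitions all nonzero
    displacements.
    """
    dx, dy, dz = np.asarray(delta, dtype=float)
    if dx == 0.0 and dy == 0.0 and dz == 0.0:
        raise ValueError("octant undefined for zero displacement")
    ap = "Ant" if dx >= 0 else "Post"
    si = "Sup" if dz >= 0 else "Inf"
    lr = "R" if dy >= 0 else "L"
    return f"{ap}{si}{lr}"


def lr_angle_and_bin(delta: np.ndarray) -> tuple[float, int | None]:
    """Signed left-right angle (rightward positive) and its 10° bin.

    The angle is that of the horizontal projection of ``delta`` against the
    anterior axis. Bins are half-open ``[a, a+10°)`` covering [−30°, 30°);
    samples outside the range (including retraction movements) get ``None``
    and are excluded from left-right analyses.
    """
    dx, dy, dz = np.asarray(delta, dtype=float)
    if dx == 0.0 and dy == 0.0:
        return float("nan"), None
    angle = float(np.degrees(np.arctan2(dy, dx)))
    if -30.0 <= angle < 30.0:
        return angle, int(np.floor((angle + 30.0) / 10.0))
    return angle, None


def yaw_pitch(delta: np.ndarray) -> tuple[float, float]:
    """Yaw (transverse rotation, rightward positive) and pitch (elevation).

    Conventional spherical decomposition of the displacement: yaw is the
    signed angle of the horizontal projection against the anterior axis,
    pitch the elevation against the horizontal plane. Both in degrees.
    """
    dx, dy, dz = np.asarray(delta, dtype=float)
    if dx == 0.0 and dy == 0.0 and dz == 0.0:
        raise ValueError("yaw/pitch undefined for zero displacement")
    yaw = float(np.degrees(np.arctan2(dy, dx)))
    pitch = float(np.degrees(np.arctan2(dz, np.hypot(dx, dy))))
    return yaw, pitch


def direction_sample(traj: MarkerTrajectory, t1: float, dt: float = 0.100) -> DirectionSample:
    """Direction of motion over ``[t1, t1 + dt]``.

    Computes theta from the position vectors at the interval endpoints and
    all categorical labels from the displacement. A zero displacement yields
    ``u = None`` and ``octant = None`` (undefined-direction flag).
    """
    v1 = traj.at(t1)
    v2 = traj.at(t1 + dt)
    delta = v2 - v1
    theta = theta_3d(v1, v2)
    norm = np.linalg.norm(delta)
    if norm > 0.0:
        u = delta / norm
        octant = octant_label(delta)
        lr_angle, lr_bin = lr_angle_and_bin(delta)
        yaw, pitch = yaw_pitch(delta)
    else:
        u, octant, lr_bin = None, None, None
        lr_angle = yaw = pitch = float("nan")
    return DirectionSample(
        t1=float(t1), t2=float(t1 + dt), v1=v1, v2=v2, delta=delta,
        theta=theta, u=u, octant=octant, lr_angle=lr_angle, lr_bin=lr_bin,
        yaw=yaw, pitch=pitch,
    )


def tile_direction_samples(
    traj: MarkerTrajectory,
    intervals: Sequence[tuple[float, float]],
    dt: float = 0.100,
) -> pd.DataFrame:
    """Tile consecutive non-overlapping ``dt`` windows within each interval.

    ``intervals`` are (start, end) times of annotated gape cycles (feeding).
    Returns one row per window with direction columns; zero-displacement
    windows are kept with null labels so callers can filter explicitly.
    """
    rows = []
    t_last = traj.time[-1]
    for start, end in intervals:
        t = start
        while t + dt <= min(end, t_last) + 1e-9:
            s = direction_sample(traj, t, dt)
            rows.append({
                "t1": s.t1, "t2": s.t2,
                "dx": s.delta[0], "dy": s.delta[1], "dz": s.delta[2],
                "theta_deg": s.theta, "octant": s.octant,
                "lr_angle_deg": s.lr_angle, "lr_bin": s.lr_bin,
                "yaw_deg": s.yaw, "pitch_deg": s.pitch,
            })
            t += dt
    return pd.DataFrame(rows)


def lick_summaries(
    traj: MarkerTrajectory,
    licks: Sequence[dict],
    sd_threshold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lick endpoint metrics and per-spout endpoint variance.

    Each lick annotation must provide ``spout`` (one of L/M/R),
    ``min_protrusion_t`` and ``max_protrusion_t`` (seconds). The endpoint is
    the marker position at maximum protrusion. A lick is *failed* when its
    endpoint deviates from its spout's mean endpoint by more than
    ``sd_threshold`` standard deviations along any axis. Mean speed is the
    path length between minimum and maximum protrusion divided by duration.

    Returns
    -------
    summaries : DataFrame, one row per lick
        Columns: spout, min_protrusion_t, max_protrusion_t, x/y/z endpoint,
        endpoint_dist_from_mean (mm), failed, mean_speed (mm/s).
    variances : DataFrame indexed by spout
        Per-axis endpoint variance (var_x, var_y, var_z) and lick count.
    """
    if not licks:
        raise ValueError("no licks provided")
    recs = []
    for lk in licks:
        if "spout" not in lk or lk["spout"] not in ("L", "M", "R"):
            raise ValueError(f"missing or invalid spout label in lick annotation: {lk!r}")
        t_min = float(lk["min_protrusion_t"])
        t_max = float(lk["max_protrusion_t"])
        if not t_min < t_max:
            raise ValueError("min_protrusion_t must precede max_protrusion_t")
        endpoint = traj.at(t_max)
        i0 = int(round((t_min - traj.time[0]) * traj.fs))
        i1 = int(round((t_max - traj.time[0]) * traj.fs))
        path = traj.position[i0:i1 + 1]
        path_len = float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))
        recs.append({
            "spout": lk["spout"], "min_protrusion_t": t_min, "max_protrusion_t": t_max,
            "x_mm": endpoint[0], "y_mm": endpoint[1], "z_mm": endpoint[2],
            "mean_speed": path_len / (t_max - t_min),
        })
    df = pd.DataFrame(recs)

    var_rows = {}
    dist = np.full(len(df), np.nan)
    failed = np.zeros(len(df), dtype=bool)
    for spout, grp in df.groupby("spout"):
        if len(grp) < 2:
            raise ValueError(f"need at least 2 licks per spout for SD estimation (spout {spout})")
        pts = grp[["x_mm", "y_mm", "z_mm"]].to_numpy()
        mean = pts.mean(axis=0)
        sd = pts.std(axis=0, ddof=1)
        dev = pts - mean
        dist[grp.index] = np.linalg.norm(dev, axis=1)
        # zero SD on an axis: only exact hits pass, any deviation fails
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(dev) / sd
        failed[grp.index] = np.any(np.where(sd > 0, z > sd_threshold, np.abs(dev) > 0), axis=1)
        var_rows[spout] = {
            "var_x": pts[:, 0].var(ddof=1), "var_y": pts[:, 1].var(ddof=1),
            "var_z": pts[:, 2].var(ddof=1), "n_licks": len(grp),
        }
    df["endpoint_dist_from_mean"] = dist
    df["failed"] = failed
    variances = pd.DataFrame.from_dict(var_rows, orient="index").rename_axis("spout")
    return df, variances


def balance_direction_samples(
    samples: pd.DataFrame,
    label_col: str = "octant",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Equalise sample counts across direction labels.

    Downsamples every label to the minimum per-label count, without
    replacement, with a seeded generator. Raises if any label of the
    column's observed set is empty after dropping null labels.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    valid = samples.dropna(subset=[label_col])
    if valid.empty:
        raise ValueError("no labelled samples")
    counts = valid[label_col].value_counts()
    if label_col == "octant":
        missing = [o for o in OCTANTS if o not in counts.index]
        if missing:
            raise ValueError(f"empty octant(s): {', '.join(missing)}")
    n = int(counts.min())
    parts = []
    for label in sorted(counts.index.astype(str)):
        grp = valid[valid[label_col].astype(str) == label]
        idx = rng.choice(grp.index.to_numpy(), size=n, replace=False)
        parts.append(valid.loc[np.sort(idx)])
    return pd.concat(parts).sort_index()


def kinematic_comparison(control: np.ndarray, test: np.ndarray) -> dict[str, float]:
    """Two-tailed t-test on means and F-test on variances of two samples.

    Used to compare kinematic performance (e.g. endpoint distances, speeds)
    between control and nerve-block conditions. The F statistic is the ratio
    of sample variances; its two-tailed p-value doubles the smaller tail.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(test, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    t_stat, t_p = stats.ttest_ind(a, b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return {"t_stat": float(t_stat), "t_test_p": float(t_p),
                "f_stat": float("nan"), "f_test_p": float("nan")}
    f = va / vb if vb > 0 else np.inf
    dfn, dfd = a.size - 1, b.size - 1
    if np.isinf(f):
        f_p = 0.0
    else:
        f_p = 2.0 * min(stats.f.cdf(f, dfn, dfd), stats.f.sf(f, dfn, dfd))
        f_p = min(f_p, 1.0)
    return {"t_stat": float(t_stat), "t_test_p": float(t_p),
            "f_stat": float(f), "f_test_p": float(f_p)}
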