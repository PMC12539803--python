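"""Synthetic session generator with known ground-truth directional tuning.

Emulates the study conditions of natural macaque orofacial behavior:

* **Feeding** — rhythmic gape cycles (~2 Hz). The tongue-tip trajectory is a
  smooth asymmetric protrusion–retraction oscillation with a coupled vertical
  component and low-amplitude lateral jitter, so instantaneous 100 ms
  movement directions are biased toward the anterior-superior octants during
  the (slower) protrusive phase and posterior-inferior during retraction.
* **Drinking** — discrete licks toward one of three juice spouts (left,
  middle, right); the endpoint of each lick scatters isotropically around
  its spout with a configurable SD.
* **Neurons** — inhomogeneous Poisson processes. Tuned neurons follow a
  rectified cosine rate model, lambda(t) = max(0, b0 + k * (u(t) . pd)),
  where u(t) is the unit movement direction over the current 100 ms window
  and pd the neuron's preferred direction; untuned neurons fire at the
  constant baseline b0. This is the minimal generative model whose fitted
  tuning curve is cosine and whose spike counts have Fano factor ~ 1.
* **Nerve block** — loss of oral tactile feedback is emulated by scaling
  endpoint scatter up, movement speed down, and the tuned fraction down,
  and by jittering each surviving preferred direction with a von
  Mises-Fisher kernel (both "lost" and shifted tuning). A *sham* session is
  generated exactly like a control session; only its seed distinguishes it.

Identical ``SimConfig`` + seed give a bit-identical session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import vonmises_fisher

from .io import AREAS, SPOUTS, Session
from .kinematics import MarkerTrajectory

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_feeding_kinematics",
    "generate_drinking_kinematics",
    "generate_spikes",
    "generate_session",
    "simulate_rate_samples",
    "simulate_spout_rate_samples",
    "sample_octant_directions",
]

_WINDOW_S = 0.100  # direction/rate window used by the encoding model


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic session.

    Rates are spikes/s, lengths mm, times s. ``tuned_fraction`` and
    ``n_neurons_per_area`` are keyed by cortical area; the defaults give a
    50-neuron population with motor areas (rMIo/cMIo) more often tuned than
    somatosensory areas (SIo 3a/3b and 1/2), mirroring the recorded
    populations at desk scale.
    """

    behavior: str = "feeding"
    condition: str = "control"
    subject: str = "sim"
    n_trials: int = 10
    trial_dur: float = 10.0
    n_neurons_per_area: dict = field(default_factory=lambda: {
        "rMIo": 10, "cMIo": 20, "SIo3ab": 8, "SIo12": 12})
    baseline_rate: float = 20.0
    modulation_depth: float = 20.0
    tuned_fraction: dict = field(default_factory=lambda: {
        "rMIo": 0.8, "cMIo": 0.8, "SIo3ab": 0.52, "SIo12": 0.52})
    # preferred directions cluster toward anterior-superior-left movements
    pd_mode: tuple = (1.0, -1.0, 1.0)
    pd_kappa: float = 2.0
    # feeding kinematics
    cycle_freq_hz: float = 2.0
    cycle_amp_mm: tuple = (10.0, 1.5, 6.0)  # anterior, lateral-jitter, vertical amplitudes
    protrusion_fraction: float = 0.6        # fraction of each cycle spent protruding
    # drinking kinematics
    spout_positions_mm: dict = field(default_factory=lambda: {
        "L": (10.0, -8.0, -2.0), "M": (14.0, 0.0, -2.0), "R": (10.0, 8.0, -2.0)})
    rest_position_mm: tuple = (2.0, 0.0, -4.0)
    lick_rate_hz: float = 1.5
    endpoint_sd_mm: float = 0.8
    # nerve-block multipliers
    block_endpoint_sd_scale: float = 3.0
    block_speed_scale: float = 0.7
    block_tuned_fraction_scale: float = 0.6
    block_pd_rotation_kappa: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.behavior not in ("feeding", "drinking"):
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.condition not in ("control", "nerve_block", "sham"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_trials <= 0 or self.trial_dur <= 0:
            raise ValueError("n_trials and trial_dur must be positive")
        if self.cycle_freq_hz <= 0 or self.lick_rate_hz <= 0:
            raise ValueError("cycle and lick frequencies must be positive")
        if self.baseline_rate < 0 or self.modulation_depth < 0:
            raise ValueError("rates must be nonnegative")
        if self.endpoint_sd_mm < 0:
            raise ValueError("endpoint SD must be nonnegative")
        for area, frac in self.tuned_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"tuned_fraction[{area}] outside [0, 1]")
        if not 0.0 < self.protrusion_fraction < 1.0:
            raise ValueError("protrusion_fraction must lie in (0, 1)")
        pts = list(self.spout_positions_mm.values())
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.allclose(pts[i], pts[j]):
                    raise ValueError("spout positions must be distinct")

    @property
    def n_neurons(self) -> int:
        return sum(self.n_neurons_per_area.values())


@dataclass(frozen=True)
class GroundTruth:
    """True tuning of every simulated neuron plus per-trial direction labels."""

    neuron_ids: np.ndarray          # (n,) str
    areas: np.ndarray               # (n,) str
    tuned: np.ndarray               # (n,) bool
    pd: np.ndarray                  # (n, 3) unit vectors (rows of untuned neurons are zero)
    b0: np.ndarray                  # (n,) baseline, spikes/s
    k: np.ndarray                   # (n,) modulation depth, spikes/s
    trial_labels: list              # per trial: spout label (drinking) or None

    def as_dict(self) -> dict:
        return {
            "neuron_ids": self.neuron_ids.tolist(), "areas": self.areas.tolist(),
            "tuned": self.tuned.tolist(), "pd": self.pd.tolist(),
            "b0": self.b0.tolist(), "k": self.k.tolist(),
            "trial_labels": self.trial_labels,
        }


def _cycle_waveform(tau: np.ndarray, rise: float) -> np.ndarray:
    """Smooth asymmetric oscillation on phase ``tau`` in [0, 1).

    Rises from −1 to +1 over the fraction ``rise`` of the cycle (protrusion)
    and falls back over the remainder (retraction); C1-continuous at the
    turning points.
    """
    s = np.empty_like(tau)
    up = tau < rise
    s[up] = -np.cos(np.pi * tau[up] / rise)
    s[~up] = np.cos(np.pi * (tau[~up] - rise) / (1.0 - rise))
    return s


def generate_feeding_kinematics(cfg: SimConfig, rng: np.random.Generator
                                ) -> tuple[MarkerTrajectory, list[dict]]:
    """Rhythmic feeding trajectory at 200 Hz plus gape-cycle annotations.

    Returns the tongue-tip trajectory and one trial dict per trial with
    annotated cycle boundaries (all cycles labelled ``chew``; cycle-type
    classification is manual in real data and not modelled).
    """
    cfg.validate()
    fs = 200.0
    f = cfg.cycle_freq_hz
    amp_x, amp_y, amp_z = cfg.cycle_amp_mm
    if cfg.condition == "nerve_block":
        amp_x, amp_y, amp_z = (a * cfg.block_speed_scale for a in cfg.cycle_amp_mm)
    n_per_trial = int(round(cfg.trial_dur * fs))
    times, positions, trials = [], [], []
    for tr in range(cfg.n_trials):
        t0 = tr * cfg.trial_dur
        t = t0 + np.arange(n_per_trial) / fs
        tau = ((t - t0) * f) % 1.0
        # per-cycle amplitude jitter keeps cycles from being carbon copies;
        # the vertical component lags the anterior one by a per-cycle random
        # fraction of the cycle, so movement direction is mostly
        # anterior-superior / posterior-inferior but all octants occur
        cyc_idx = np.floor((t - t0) * f).astype(int)
        n_cycles = cyc_idx.max() + 1
        amp_jit = rng.uniform(0.8, 1.2, size=n_cycles)[cyc_idx]
        amp_jit_z = rng.uniform(0.8, 1.2, size=n_cycles)[cyc_idx]
        lag = rng.uniform(0.05, 0.20, size=n_cycles)[cyc_idx]
        s = _cycle_waveform(tau, cfg.protrusion_fraction) * amp_jit
        s_z = _cycle_waveform((tau - lag) % 1.0, cfg.protrusion_fraction) * amp_jit_z
        phase_y, phase_x, phase_z = rng.uniform(0, 2 * np.pi, size=3)
        x = 6.0 + 0.5 * amp_x * s + 0.03 * amp_x * np.sin(2 * np.pi * 3.3 * (t - t0) + phase_x)
        y = amp_y * np.sin(2 * np.pi * f * (t - t0) + phase_y)
        z = -2.0 + 0.5 * amp_z * s_z + 0.08 * amp_z * np.sin(2 * np.pi * 4.7 * (t - t0) + phase_z)
        times.append(t)
        positions.append(np.column_stack([x, y, z]))
        cycles = [{"start_s": t0 + c / f, "end_s": t0 + min((c + 1) / f, cfg.trial_dur),
                   "cycle_type": "chew"} for c in range(int(cfg.trial_dur * f))]
        trials.append({
            "trial_id": tr, "behavior": "feeding", "condition": cfg.condition,
            "start_s": t0, "end_s": t0 + cfg.trial_dur, "spout": None,
            "cycles": cycles, "min_protrusion_times_s": [], "max_protrusion_times_s": [],
        })
    traj = MarkerTrajectory(np.concatenate(times), np.vstack(positions))
    return traj, trials


def generate_drinking_kinematics(cfg: SimConfig, rng: np.random.Generator
                                 ) -> tuple[MarkerTrajectory, list[dict]]:
    """Discrete licks toward labelled spouts plus lick annotations.

    Each trial delivers juice from one spout; the tongue traces a smooth
    out-and-back path from the rest position toward a per-lick target
    (spout + isotropic endpoint scatter). Minimum protrusion is the lick
    boundary, maximum protrusion the endpoint. Under nerve block the
    endpoint SD is scaled up and the lick period stretched (slower tongue).
    """
    cfg.validate()
    fs = 200.0
    sd = cfg.endpoint_sd_mm
    period = 1.0 / cfg.lick_rate_hz
    if cfg.condition == "nerve_block":
        sd *= cfg.block_endpoint_sd_scale
        period /= cfg.block_speed_scale
    rest = np.asarray(cfg.rest_position_mm, dtype=float)
    # snap the lick period to an even number of samples so maximum
    # protrusion (mid-lick) falls exactly on a grid sample
    period = max(2, int(round(period * fs / 2.0)) * 2) / fs
    n_per_trial = int(round(cfg.trial_dur * fs))
    # balanced spout order, shuffled
    spouts = np.array([SPOUTS[i % 3] for i in range(cfg.n_trials)])
    rng.shuffle(spouts)
    times, positions, trials = [], [], []
    for tr in range(cfg.n_trials):
        t0 = tr * cfg.trial_dur
        t = t0 + np.arange(n_per_trial) / fs
        spout = str(spouts[tr])
        target_base = np.asarray(cfg.spout_positions_mm[spout], dtype=float)
        n_licks = int(np.floor(cfg.trial_dur / period))
        pos = np.tile(rest, (n_per_trial, 1))
        min_ts, max_ts = [], []
        for lk in range(n_licks):
            lick_t0 = lk * period
            target = target_base + rng.normal(0.0, sd, size=3)
            idx = (t - t0 >= lick_t0) & (t - t0 < lick_t0 + period)
            tau = ((t[idx] - t0) - lick_t0) / period
            h = np.sin(np.pi * tau) ** 2
            pos[idx] = rest + h[:, None] * (target - rest)
            min_ts.append(t0 + lick_t0)
            max_ts.append(t0 + lick_t0 + 0.5 * period)
        times.append(t)
        positions.append(pos)
        trials.append({
            "trial_id": tr, "behavior": "drinking", "condition": cfg.condition,
            "start_s": t0, "end_s": t0 + cfg.trial_dur, "spout": spout,
            "cycles": [], "min_protrusion_times_s": min_ts,
            "max_protrusion_times_s": max_ts,
        })
    traj = MarkerTrajectory(np.concatenate(times), np.vstack(positions))
    return traj, trials


def make_ground_truth(cfg: SimConfig, rng: np.random.Generator,
                      trial_labels: list) -> GroundTruth:
    """Draw per-neuron tuning parameters.

    Tuned flags are Bernoulli per area (nerve block scales the fraction
    down); preferred directions are von Mises-Fisher around ``pd_mode``,
    additionally jittered by a vMF kernel under nerve block; baselines and
    modulation depths get ±30% lognormal-free uniform jitter.
    """
    ids, areas, tuned, pds, b0s, ks = [], [], [], [], [], []
    mode = np.asarray(cfg.pd_mode, dtype=float)
    mode = mode / np.linalg.norm(mode)
    for area in AREAS:
        n = cfg.n_neurons_per_area.get(area, 0)
        frac = cfg.tuned_fraction.get(area, 0.0)
        if cfg.condition == "nerve_block":
            frac *= cfg.block_tuned_fraction_scale
        for j in range(n):
            ids.append(f"{area}_{j:03d}")
            areas.append(area)
            is_tuned = bool(rng.random() < frac)
            tuned.append(is_tuned)
            if is_tuned:
                pd_vec = vonmises_fisher(mode, cfg.pd_kappa).rvs(1, random_state=rng)[0]
                if cfg.condition == "nerve_block":
                    pd_vec = vonmises_fisher(pd_vec, cfg.block_pd_rotation_kappa).rvs(
                        1, random_state=rng)[0]
                pds.append(pd_vec / np.linalg.norm(pd_vec))
                ks.append(cfg.modulation_depth * rng.uniform(0.7, 1.3))
            else:
                pds.append(np.zeros(3))
                ks.append(0.0)
            b0s.append(cfg.baseline_rate * rng.uniform(0.7, 1.3))
    return GroundTruth(
        neuron_ids=np.array(ids), areas=np.array(areas),
        tuned=np.array(tuned, dtype=bool), pd=np.array(pds),
        b0=np.array(b0s), k=np.array(ks), trial_labels=trial_labels,
    )


def _window_directions(traj: MarkerTrajectory, window: float = _WINDOW_S
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Unit movement direction per consecutive non-overlapping window.

    Returns window start times and (W, 3) unit vectors (zero rows where the
    marker did not move).
    """
    fs = traj.fs
    step = int(round(window * fs))
    n_win = (traj.position.shape[0] - 1) // step
    starts = traj.time[0] + np.arange(n_win) * window
    p = traj.position
    delta = p[np.arange(1, n_win + 1) * step] - p[np.arange(n_win) * step]
    norm = np.linalg.norm(delta, axis=1, keepdims=True)
    u = np.divide(delta, norm, out=np.zeros_like(delta), where=norm > 0)
    return starts, u


def generate_spikes(traj: MarkerTrajectory, gt: GroundTruth, cfg: SimConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Inhomogeneous Poisson spike trains from the rectified cosine model.

    The rate is piecewise constant over consecutive 100 ms windows:
    ``max(0, b0 + k * (u . pd))`` for tuned neurons, ``b0`` for untuned.
    Spike times are uniform within each window; within a neuron they are
    strictly increasing.
    """
    if np.any(gt.b0 < 0) or np.any(gt.k < 0):
        raise ValueError("baseline and modulation depth must be nonnegative")
    starts, u = _window_directions(traj)
    # (W, n) rates
    rates = np.maximum(0.0, gt.b0[None, :] + (u @ gt.pd.T) * gt.k[None, :])
    counts = rng.poisson(rates * _WINDOW_S)
    recs_id, recs_area, recs_t = [], [], []
    for j, nid in enumerate(gt.neuron_ids):
        c = counts[:, j]
        nz = np.nonzero(c)[0]
        if nz.size == 0:
            continue
        offsets = rng.random(int(c[nz].sum())) * _WINDOW_S
        t = np.repeat(starts[nz], c[nz]) + offsets
        t = np.sort(t)
        # enforce strict increase in the (measure-zero) event of a tie
        eps = 1e-9
        for i in range(1, t.size):
            if t[i] <= t[i - 1]:
                t[i] = t[i - 1] + eps
        recs_id.append(np.full(t.size, nid))
        recs_area.append(np.full(t.size, gt.areas[j]))
        recs_t.append(t)
    if recs_id:
        df = pd.DataFrame({
            "neuron_id": np.concatenate(recs_id),
            "area": np.concatenate(recs_area),
            "spike_time_s": np.concatenate(recs_t),
        })
    else:
        df = pd.DataFrame(columns=["neuron_id", "area", "spike_time_s"])
    return df.sort_values(["neuron_id", "spike_time_s"], kind="stable").reset_index(drop=True)


def generate_session(cfg: SimConfig) -> Session:
    """Generate a complete synthetic session (kinematics, spikes, labels).

    Deterministic: identical config (including seed) gives a bit-identical
    session. The ground truth is attached as a sidecar dict.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if cfg.behavior == "feeding":
        traj, trials = generate_feeding_kinematics(cfg, rng)
        labels = [None] * cfg.n_trials
    else:
        traj, trials = generate_drinking_kinematics(cfg, rng)
        labels = [tr["spout"] for tr in trials]
    gt = make_ground_truth(cfg, rng, labels)
    spikes = generate_spikes(traj, gt, cfg, rng)
    kin = pd.DataFrame({
        "time_s": traj.time, "marker_id": "tongue_tip",
        "x_mm": traj.position[:, 0], "y_mm": traj.position[:, 1],
        "z_mm": traj.position[:, 2],
    })
    gt_dict = gt.as_dict()
    # JSON round-trip normalises nested tuples to lists once, so the sidecar
    # compares equal after a write/read cycle
    gt_dict["config"] = json.loads(json.dumps(asdict(cfg)))
    return Session(
        subject=cfg.subject, behavior=cfg.behavior, condition=cfg.condition,
        kinematics=kin, spikes=spikes, trials=trials, ground_truth=gt_dict,
    )


def simulate_spout_rate_samples(
    n_neurons: int,
    trials_per_class: int = 60,
    baseline: float = 10.0,
    modulation: float = 25.0,
    window: float = 0.5,
    target_kappa: float = 50.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Drinking-style 3-class rate samples from cosine neurons.

    Movement directions concentrate (von Mises-Fisher, ``target_kappa``)
    around three discrete spout targets at yaw −45°, 0°, +45° in the
    horizontal plane; rates are Poisson counts over ``window`` seconds from
    the rectified cosine model with uniformly distributed preferred
    directions. Returns (rates (S, N), spout labels (S,), directions (S, 3),
    preferred directions (N, 3)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = {
        "L": np.array([np.cos(np.radians(-45)), np.sin(np.radians(-45)), 0.0]),
        "M": np.array([1.0, 0.0, 0.0]),
        "R": np.array([np.cos(np.radians(45)), np.sin(np.radians(45)), 0.0]),
    }
    us, labels = [], []
    for lab, t in targets.items():
        u = vonmises_fisher(t, target_kappa).rvs(trials_per_class, random_state=rng)
        us.append(np.atleast_2d(u))
        labels.extend([lab] * trials_per_class)
    u = np.vstack(us)
    pds = rng.standard_normal((n_neurons, 3))
    pds /= np.linalg.norm(pds, axis=1, keepdims=True)
    lam = np.maximum(0.0, baseline + (u @ pds.T) * modulation)
    rates = rng.poisson(lam * window) / window
    return rates.astype(float), np.array(labels), u, pds


def sample_octant_directions(samples_per_octant: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors uniform within each octant, with octant labels.

    Returns (S, 3) directions and (S,) octant label strings,
    S = 8 * samples_per_octant.
    """
    from .kinematics import octant_label
    signs = np.array([[sx, sy, sz] for sx in (1, -1) for sz in (1, -1) for sy in (1, -1)],
                     dtype=float)
    us, labels = [], []
    for sign in signs:
        g = np.abs(rng.standard_normal((samples_per_octant, 3)))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        u = g * sign
        us.append(u)
        labels.extend(octant_label(v) for v in u)
    return np.vstack(us), np.array(labels)


def simulate_rate_samples(
    n_neurons: int,
    samples_per_octant: int = 50,
    baseline: float = 20.0,
    modulation: float = 20.0,
    tuned_fraction: float = 1.0,
    window: float = _WINDOW_S,
    pd_mode: tuple | None = None,
    pd_kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Balanced direction-labelled firing-rate samples from cosine neurons.

    A direction-level shortcut past full-session generation: draws unit
    movement directions uniformly within each octant and Poisson spike
    counts over ``window`` from the rectified cosine model, returning rates
    in spikes/s. With ``modulation = 0`` (or ``tuned_fraction = 0``) the
    rates are direction-independent — the null population used for
    calibration checks. Preferred directions are uniform on the sphere when
    ``pd_mode`` is None, else von Mises-Fisher around it.

    Returns (rates (S, N), octant labels (S,), directions (S, 3), ground truth).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u, labels = sample_octant_directions(samples_per_octant, rng)
    tuned = rng.random(n_neurons) < tuned_fraction
    if pd_mode is None:
        pds = rng.standard_normal((n_neurons, 3))
        pds /= np.linalg.norm(pds, axis=1, keepdims=True)
    else:
        mode = np.asarray(pd_mode, dtype=float)
        mode /= np.linalg.norm(mode)
        pds = vonmises_fisher(mode, pd_kappa).rvs(n_neurons, random_state=rng)
        pds = np.atleast_2d(pds)
    pds[~tuned] = 0.0
    k = np.where(tuned, modulation, 0.0)
    lam = np.maximum(0.0, baseline + (u @ pds.T) * k[None, :])
    rates = rng.poisson(lam * window) / window
    gt = GroundTruth(
        neuron_ids=np.array([f"sim_{j:04d}" for j in range(n_neurons)]),
        areas=np.array(["cMIo"] * n_neurons), tuned=tuned, pd=pds,
        b0=np.full(n_neurons, float(baseline)), k=k,
        trial_labels=labels.tolist(),
    )
    return rates.astype(float), labels, u, gt
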