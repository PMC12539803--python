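"""Session file formats and validation.

A *session* is one subject × behavior × condition recording: a tongue-marker
trajectory, spike trains of sorted neurons assigned to cortical areas, and
trial annotations. On disk a session is a directory with

* ``kinematics.csv`` — columns ``time_s, marker_id, x_mm, y_mm, z_mm``
* ``spikes.csv``     — columns ``neuron_id, area, spike_time_s``
* ``trials.json``    — list of trial records (see :class:`Session`)
* ``ground_truth.json`` (optional) — simulator sidecar with true tuning
* ``manifest.json``  — subject, behavior, condition, sampling rate, paths

Times are seconds, session-relative, 0 at session start; trials are closed
intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import MarkerTrajectory

__all__ = ["Session", "SessionManifest", "write_session", "read_session"]

AREAS = ("rMIo", "cMIo", "SIo3ab", "SIo12")
SPOUTS = ("L", "M", "R")
CYCLE_TYPES = ("manipulation", "s1_transport", "chew", "s2_transport", "swallow")


@dataclass
class SessionManifest:
    subject: str
    behavior: str
    condition: str
    kinematics_csv: str = "kinematics.csv"
    spikes_csv: str = "spikes.csv"
    trials_json: str = "trials.json"
    ground_truth_json: str | None = None
    sampling_rate_hz: float = 200.0
    coordinate_frame: str = "cranial; origin at posterior nasal spine; x anterior+, y right+, z superior+"


@dataclass
class Session:
    """In-memory session.

    Attributes
    ----------
    kinematics : DataFrame with columns time_s, marker_id, x_mm, y_mm, z_mm.
    spikes : DataFrame with columns neuron_id, area, spike_time_s.
    trials : list of dicts with keys trial_id, behavior, condition, start_s,
        end_s, and either ``cycles`` (feeding: list of
        {start_s, end_s, cycle_type}) or ``spout`` plus
        ``min_protrusion_times_s`` / ``max_protrusion_times_s`` (drinking).
    ground_truth : optional dict from the simulator (true PDs etc.).
    """

    subject: str
    behavior: str
    condition: str
    kinematics: pd.DataFrame
    spikes: pd.DataFrame
    trials: list[dict]
    ground_truth: dict | None = None
    sampling_rate_hz: float = 200.0

    def trajectory(self, marker_id: str = "tongue_tip") -> MarkerTrajectory:
        k = self.kinematics[self.kinematics["marker_id"] == marker_id]
        if k.empty:
            raise ValueError(f"no samples for marker {marker_id!r}")
        return MarkerTrajectory(k["time_s"].to_numpy(), k[["x_mm", "y_mm", "z_mm"]].to_numpy())

    def spike_times(self) -> dict[str, np.ndarray]:
        """Spike times per neuron id, sorted."""
        return {nid: grp["spike_time_s"].to_numpy()
                for nid, grp in self.spikes.groupby("neuron_id", sort=True)}

    def neuron_areas(self) -> dict[str, str]:
        return dict(self.spikes.groupby("neuron_id", sort=True)["area"].first())


def write_session(session: Session, directory: str | Path) -> Path:
    """Write a session directory; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    session.kinematics.to_csv(directory / "kinematics.csv", index=False)
    session.spikes.to_csv(directory / "spikes.csv", index=False)
    with open(directory / "trials.json", "w") as fh:
        json.dump(session.trials, fh, indent=1)
    manifest = SessionManifest(
        subject=session.subject, behavior=session.behavior,
        condition=session.condition, sampling_rate_hz=session.sampling_rate_hz,
    )
    if session.ground_truth is not None:
        manifest.ground_truth_json = "ground_truth.json"
        with open(directory / "ground_truth.json", "w") as fh:
            json.dump(session.ground_truth, fh, indent=1)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest.__dict__, fh, indent=1)
    return directory / "manifest.json"


def _validate_spikes(spikes: pd.DataFrame) -> None:
    required = {"neuron_id", "area", "spike_time_s"}
    if not required.issubset(spikes.columns):
        raise ValueError(f"spikes CSV missing columns {required - set(spikes.columns)}")
    bad = spikes.index[spikes["spike_time_s"] < 0]
    if len(bad):
        raise ValueError(f"negative spike time at row(s) {list(bad[:5])}")
    unknown = set(spikes["area"].unique()) - set(AREAS)
    if unknown:
        raise ValueError(f"unknown area label(s) {sorted(unknown)}; expected {AREAS}")
    for nid, grp in spikes.groupby("neuron_id"):
        t = grp["spike_time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            row = grp.index[1:][np.diff(t) < 0][0]
            raise ValueError(f"non-monotone spike times for neuron {nid} at row {row}")


def _validate_trials(trials: list[dict]) -> None:
    seen = set()
    for tr in trials:
        tid = tr.get("trial_id")
        if tid in seen:
            raise ValueError(f"duplicate trial id {tid}")
        seen.add(tid)
        if not (0 <= tr["start_s"] < tr["end_s"]):
            raise ValueError(f"trial {tid}: invalid interval [{tr['start_s']}, {tr['end_s']}]")
        spout = tr.get("spout")
        if spout is not None and spout not in SPOUTS:
            raise ValueError(f"trial {tid}: spout label {spout!r} outside {SPOUTS}")
        for key in ("min_protrusion_times_s", "max_protrusion_times_s"):
            for t in tr.get(key) or []:
                if not (tr["start_s"] - 1e-9 <= t <= tr["end_s"] + 1e-9):
                    raise ValueError(f"trial {tid}: annotation time {t} outside trial interval")
        for cyc in tr.get("cycles") or []:
            if cyc.get("cycle_type") is not None and cyc["cycle_type"] not in CYCLE_TYPES:
                raise ValueError(f"trial {tid}: unknown cycle type {cyc['cycle_type']!r}")
            if not (tr["start_s"] - 1e-9 <= cyc["start_s"] < cyc["end_s"] <= tr["end_s"] + 1e-9):
                raise ValueError(f"trial {tid}: cycle outside trial interval")


def read_session(manifest_path: str | Path) -> Session:
    """Read and validate a session directory from its manifest."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        m = json.load(fh)
    base = manifest_path.parent
    kinematics = pd.read_csv(base / m["kinematics_csv"])
    spikes = pd.read_csv(base / m["spikes_csv"])
    with open(base / m["trials_json"]) as fh:
        trials = json.load(fh)
    _validate_spikes(spikes)
    _validate_trials(trials)
    gt = None
    if m.get("ground_truth_json"):
        with open(base / m["ground_truth_json"]) as fh:
            gt = json.load(fh)
    return Session(
        subject=m["subject"], behavior=m["behavior"], condition=m["condition"],
        kinematics=kinematics, spikes=spikes, trials=trials, ground_truth=gt,
        sampling_rate_hz=float(m.get("sampling_rate_hz", 200.0)),
    )
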