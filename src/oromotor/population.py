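"""Factor-analysis latent trajectories of population activity.

Spike counts in 10 ms bins are modelled as y ~ N(mu, C'C + R) with a diagonal
noise matrix R: the m latent factors capture the *shared* variance of the
population, and trial-averaged counts projected through the model's
posterior mapping form low-dimensional neural trajectories per movement
direction. Direction separation is quantified by the per-bin Euclidean
inter-trajectory distance (first 20 factors by default), the geometric index
GI = (d1 − d2)/(d1 + d2) contrasting two mean distances, and the cumulative
path length travelled from trial start to end.

The EM fit itself is delegated to scikit-learn's ``FactorAnalysis``; this
module owns the binning/smoothing pipeline, cross-validated dimensionality
selection, projection, and the trajectory geometry statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import FactorAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold

from .io import Session

__all__ = [
    "LatentModel",
    "TrajectorySet",
    "prepare_counts",
    "group_counts_by_direction",
    "fa_fit",
    "fa_select_dim",
    "latent_trajectories",
    "inter_trajectory_distance",
    "geometric_index",
    "trajectory_length",
    "variance_explained",
    "subsample_controls",
]


@dataclass
class LatentModel:
    """Fitted factor-analysis model y ~ N(mu, C'C + R).

    ``C`` is the (m x n) loading matrix mapping m latent factors onto the
    spike counts of n neurons; ``R`` holds the diagonal independent noise
    variances. ``loglik_trace`` records the per-EM-iteration log-likelihood
    (non-decreasing up to numerical round-off).
    """

    mu: np.ndarray            # (n,)
    C: np.ndarray             # (m, n)
    R: np.ndarray             # (n,) diagonal noise variances
    m: int
    loglik_trace: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        if np.any(self.R <= 0):
            raise ValueError("R must be strictly positive")
        if self.C.shape[0] != self.m or self.C.shape[1] != self.mu.size:
            raise ValueError("C must be (m, n)")

    def posterior_matrix(self) -> np.ndarray:
        """(m x n) matrix W with E[z | y] = W (y − mu)."""
        CRinv = self.C / self.R[None, :]
        G = np.eye(self.m) + CRinv @ self.C.T
        return np.linalg.solve(G, CRinv)

    def project(self, Y: np.ndarray) -> np.ndarray:
        """Posterior factor expectations for rows of ``Y`` (obs x n)."""
        return (np.asarray(Y, dtype=float) - self.mu) @ self.posterior_matrix().T

    def shared_covariance(self) -> np.ndarray:
        return self.C.T @ self.C

    def to_hdf5(self, path, group: str = "latent_model") -> None:
        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            for name in ("mu", "C", "R", "loglik_trace"):
                g.create_dataset(name, data=getattr(self, name))
            g.attrs["m"] = self.m
            g.attrs["converged"] = self.converged

    @classmethod
    def from_hdf5(cls, path, group: str = "latent_model") -> "LatentModel":
        with h5py.File(path, "r") as fh:
            g = fh[group]
            return cls(mu=g["mu"][:], C=g["C"][:], R=g["R"][:],
                       m=int(g.attrs["m"]), loglik_trace=g["loglik_trace"][:],
                       converged=bool(g.attrs["converged"]))


@dataclass
class TrajectorySet:
    """Trial-averaged latent trajectories per direction label."""

    trajectories: dict[str, np.ndarray]   # label -> (bins, m)
    bin_s: float = 0.010
    m: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.trajectories.values()}
        if len(shapes) > 1:
            raise ValueError("all trajectories must share the bin grid and m")
        if self.trajectories and self.m == 0:
            self.m = next(iter(self.trajectories.values())).shape[1]

    def to_hdf5(self, path, group: str = "trajectories") -> None:
        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            g.attrs["bin_s"] = self.bin_s
            g.attrs["m"] = self.m
            for label, arr in self.trajectories.items():
                g.create_dataset(label, data=arr)


def prepare_counts(
    session: Session,
    bin_s: float = 0.010,
    smooth_sd: float = 0.010,
    min_rate: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned, smoothed spike counts per analysis window.

    Windows follow the tuning conventions: 100 ms (10 bins) movement windows
    labelled by octant for feeding, 500 ms (50 bins) windows around minimum
    protrusion labelled by spout for drinking. Counts are binned at
    ``bin_s`` then smoothed along time with a Gaussian kernel of SD
    ``smooth_sd``. Neurons with session-mean rate below ``min_rate``
    (spikes/s over the analysed windows) are excluded.

    Returns
    -------
    counts : (T, bins, N) smoothed counts
    labels : (T,) direction label per window
    kept : (N,) neuron ids retained
    """
    spike_times = session.spike_times()
    neuron_ids = np.array(sorted(spike_times))
    windows, labels = [], []
    if session.behavior == "feeding":
        from .kinematics import direction_sample
        traj = session.trajectory()
        t_last = traj.time[-1]
        for tr in session.trials:
            for cyc in tr.get("cycles") or []:
                t = cyc["start_s"]
                while t + 0.100 <= min(cyc["end_s"], t_last) + 1e-9:
                    s = direction_sample(traj, t, 0.100)
                    if s.octant is not None:
                        windows.append((t, t + 0.100))
                        labels.append(s.octant)
                    t += 0.100
    else:
        for tr in session.trials:
            for t_min in tr.get("min_protrusion_times_s") or []:
                if t_min - 0.250 >= tr["start_s"] - 1e-9 and t_min + 0.250 <= tr["end_s"] + 1e-9:
                    windows.append((t_min - 0.250, t_min + 0.250))
                    labels.append(tr["spout"])
    if not windows:
        raise ValueError("no analysis windows in session")
    n_bins = int(round((windows[0][1] - windows[0][0]) / bin_s))
    lows = np.array([w[0] for w in windows])
    edges = (lows[:, None] + np.arange(n_bins + 1) * bin_s).ravel()
    counts = np.empty((len(windows), n_bins, neuron_ids.size))
    for j, nid in enumerate(neuron_ids):
        pos = np.searchsorted(spike_times[nid], edges).reshape(len(windows), n_bins + 1)
        counts[:, :, j] = np.diff(pos, axis=1)
    total_t = sum(hi - lo for lo, hi in windows)
    mean_rate = counts.sum(axis=(0, 1)) / total_t
    keep = mean_rate >= min_rate
    if not np.any(keep):
        raise ValueError("all neurons excluded by the minimum-rate threshold")
    counts = counts[:, :, keep]
    if smooth_sd > 0:
        counts = gaussian_filter1d(counts, sigma=smooth_sd / bin_s, axis=1, mode="constant")
    return counts, np.array(labels), neuron_ids[keep]


def group_counts_by_direction(counts: np.ndarray, labels: np.ndarray
                              ) -> dict[str, np.ndarray]:
    """Split a (T, bins, N) count array into {label: (T_label, bins, N)}."""
    labels = np.asarray(labels)
    return {str(l): counts[labels == l] for l in np.unique(labels)}


def fa_fit(Y: np.ndarray, m: int, tol: float = 1e-3, max_iter: int = 500) -> LatentModel:
    """Fit the m-factor model to observations ``Y`` (obs x neurons) by EM.

    Thin wrapper over scikit-learn's ``FactorAnalysis`` (LAPACK SVD per EM
    step, deterministic). Non-convergence at ``max_iter`` raises a warning
    and returns the best model so far.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[1]
    if not 0 < m < n:
        raise ValueError(f"need 0 < m < n (got m={m}, n={n})")
    if Y.shape[0] < m + 1:
        raise ValueError("need at least m + 1 observations")
    fa = FactorAnalysis(n_components=m, tol=tol, max_iter=max_iter, svd_method="lapack")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        fa.fit(Y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(f"FA EM did not converge within {max_iter} iterations; "
                          "returning best model", stacklevel=2)
    return LatentModel(
        mu=fa.mean_, C=fa.components_, R=fa.noise_variance_, m=m,
        loglik_trace=np.asarray(fa.loglike_), converged=converged,
    )


def fa_select_dim(Y: np.ndarray, candidates, folds: int = 3,
                  seed: int = 0, tol: float = 1e-3, max_iter: int = 500
                  ) -> tuple[int, dict[int, float]]:
    """Cross-validated latent dimensionality.

    Fits each candidate m on ``folds``-fold training splits and scores the
    held-out log-likelihood; returns (argmax m, {m: mean heldout loglik}).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate dimensionalities")
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < folds:
        raise ValueError("fewer observations than folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores: dict[int, float] = {}
    for m in candidates:
        vals = []
        for train, test in kf.split(Y):
            fa = FactorAnalysis(n_components=m, tol=tol, max_iter=max_iter,
                                svd_method="lapack")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                fa.fit(Y[train])
            vals.append(fa.score(Y[test]))
        scores[m] = float(np.mean(vals))
    best = max(scores, key=scores.get)
    return best, scores


def latent_trajectories(model: LatentModel,
                        counts_by_direction: dict[str, np.ndarray],
                        bin_s: float = 0.010) -> TrajectorySet:
    """Trial-average counts per direction and project into latent space.

    ``counts_by_direction`` maps labels to (trials, bins, n) arrays; empty
    directions are omitted with a warning. Projection uses the posterior
    factor expectation, a linear map, so the projection of the mean equals
    the mean of projections.
    """
    trajs = {}
    for label, arr in counts_by_direction.items():
        if arr.shape[0] == 0:
            warnings.warn(f"direction {label!r} has no trials; omitted", stacklevel=2)
            continue
        trajs[label] = model.project(arr.mean(axis=0))
    return TrajectorySet(trajectories=trajs, bin_s=bin_s, m=model.m)


def inter_trajectory_distance(traj_a: np.ndarray, traj_b: np.ndarray,
                              m: int = 20) -> dict:
    """Per-bin Euclidean distance between two latent trajectories.

    Uses the first ``min(m, available)`` factors (with a warning when fewer
    than requested are available). Returns per-bin distances, their mean,
    and a one-sample t-test p-value of the per-bin distances against zero.
    """
    a = np.asarray(traj_a, dtype=float)
    b = np.asarray(traj_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("trajectories must share the bin grid")
    avail = min(a.shape[1], b.shape[1])
    if avail < m:
        warnings.warn(f"only {avail} factors available; using them instead of {m}",
                      stacklevel=2)
    use = min(m, avail)
    d = np.linalg.norm(a[:, :use] - b[:, :use], axis=1)
    if np.allclose(d.std(), 0.0):
        p = 1.0 if np.allclose(d, 0.0) else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return {"per_bin": d, "mean": float(d.mean()), "p_vs_zero": p, "m_used": use}


def geometric_index(d1: float, d2: float) -> float:
    """Normalized contrast GI = (d1 − d2)/(d1 + d2) of two mean distances."""
    if d1 + d2 <= 0:
        raise ValueError("GI undefined for d1 + d2 <= 0")
    return float((d1 - d2) / (d1 + d2))


def trajectory_length(traj: np.ndarray) -> float:
    """Cumulative Euclidean path length of a latent trajectory."""
    t = np.asarray(traj, dtype=float)
    if t.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(t, axis=0), axis=1)))


def variance_explained(model: LatentModel, k: int | None = None) -> np.ndarray:
    """Cumulative fraction of shared variance captured by leading factors.

    Shared variance is the eigen-spectrum of C'C (equivalently the
    eigenvalues of the m x m matrix C C'); the fraction at k is the sum of
    the k largest eigenvalues over the total.
    """
    eig = np.sort(np.linalg.eigvalsh(model.C @ model.C.T))[::-1]
    cum = np.cumsum(eig) / eig.sum()
    return cum if k is None else cum[:k]


def subsample_controls(
    counts_by_direction: dict[str, np.ndarray],
    m: int,
    trials_per_dir: int = 80,
    repeats: int = 10,
    n_neurons: int | None = None,
    k_factors: int = 3,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Trial- and neuron-subsampling controls for the FA pipeline.

    Refits the m-factor model on ``repeats`` random subsamples of
    ``trials_per_dir`` trials per direction (and optionally ``n_neurons``
    neurons) and reports the cumulative shared variance explained by the
    leading ``k_factors`` factors for the full data and each subsample.
    Subsampled indices are sorted, so a subsample of the full size
    reproduces the full-data fit exactly.
    """
    rng = np.random.default_rng(seed)
    labels = sorted(counts_by_direction)
    short = {l: counts_by_direction[l].shape[0] for l in labels
             if counts_by_direction[l].shape[0] < trials_per_dir}
    if short:
        raise ValueError(f"insufficient trials for subsampling: {short} < {trials_per_dir}")
    n_total = next(iter(counts_by_direction.values())).shape[2]
    if n_neurons is not None and n_neurons > n_total:
        raise ValueError("n_neurons exceeds the population size")

    def _fit(arrs: list[np.ndarray], cols: np.ndarray | None) -> float:
        Y = np.concatenate([a.reshape(-1, a.shape[2]) for a in arrs], axis=0)
        if cols is not None:
            Y = Y[:, cols]
        model = fa_fit(Y, m=m, tol=tol, max_iter=max_iter)
        return float(variance_explained(model)[min(k_factors, m) - 1])

    rows = [{"run": "full", "variance_explained": _fit(
        [counts_by_direction[l] for l in labels], None)}]
    for rep in range(repeats):
        arrs = []
        for l in labels:
            arr = counts_by_direction[l]
            idx = np.sort(rng.choice(arr.shape[0], size=trials_per_dir, replace=False))
            arrs.append(arr[idx])
        cols = (np.sort(rng.choice(n_total, size=n_neurons, replace=False))
                if n_neurons is not None else None)
        rows.append({"run": f"subsample_{rep}", "variance_explained": _fit(arrs, cols)})
    return pd.DataFrame(rows)
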