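"""Single-neuron directional tuning statistics.

Modulation is tested with a rank-based bootstrap; tuning curves are fit with
the classic 3D cosine model f = b0 + bx*dx + by*dy + bz*dz against the
representative unit vector of each direction category, giving a preferred
direction PD = (bx, by, bz)/||(bx, by, bz)|| for neurons whose fit is
significant. Depth of tuning is summarised by the directional index
DI = (max − min)/max over per-direction mean rates, and spike-count
variability by the Fano factor (variance/mean) with a mean-matched variant
for across-group comparisons. Distribution-level tests: a spherical
Rayleigh test for nonuniform PDs on the unit sphere, a circular
concentration (k) test comparing angular PD distributions, and a chi-square
test comparing tuned proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, RegressorMixin

from .kinematics import OCTANTS, balance_direction_samples, direction_sample
from .io import Session

__all__ = [
    "RateMatrix",
    "peth",
    "bootstrap_modulation_test",
    "CosineTuning",
    "cosine_fit",
    "octant_unit_vectors",
    "directional_index",
    "drinking_pd_bootstrap",
    "fano",
    "mean_matched_fano",
    "rayleigh_test_sphere",
    "circular_k_test",
    "proportion_comparison",
    "rate_matrix_from_session",
    "tuning_summary",
]

_SQ3 = 1.0 / np.sqrt(3.0)


@dataclass
class RateMatrix:
    """Direction-labelled firing rates, samples x neurons."""

    rates: np.ndarray       # (S, N) spikes/s, nonnegative
    labels: np.ndarray      # (S,) direction label per sample
    neuron_ids: np.ndarray  # (N,)
    areas: np.ndarray       # (N,)
    behavior: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.rates.ndim != 2 or self.labels.shape[0] != self.rates.shape[0]:
            raise ValueError("rates must be (S, N) with one label per sample")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def balanced(self) -> bool:
        _, counts = np.unique(self.labels, return_counts=True)
        return bool(np.all(counts == counts[0]))


def peth(spike_times: np.ndarray, event_times: np.ndarray,
         kernel_sd: float = 0.025, window: tuple[float, float] = (-0.5, 0.5),
         bin_s: float = 0.001) -> pd.DataFrame:
    """Peri-event time histogram: event-aligned mean rate ± SE.

    Spikes are binned at ``bin_s`` per event, smoothed with a Gaussian
    kernel of SD ``kernel_sd`` (seconds), and averaged across events.
    Returns a DataFrame with columns ``time_s``, ``rate``, ``se``.
    """
    events = np.asarray(event_times, dtype=float)
    if events.size < 2:
        raise ValueError("need at least two events")
    lo, hi = window
    if not lo < hi:
        raise ValueError("empty window")
    edges = np.arange(lo, hi + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    spikes = np.asarray(spike_times, dtype=float)
    per_event = np.empty((events.size, centers.size))
    for i, ev in enumerate(events):
        counts, _ = np.histogram(spikes - ev, bins=edges)
        per_event[i] = gaussian_filter1d(counts / bin_s, sigma=kernel_sd / bin_s)
    return pd.DataFrame({
        "time_s": centers,
        "rate": per_event.mean(axis=0),
        "se": per_event.std(axis=0, ddof=1) / np.sqrt(events.size),
    })


def bootstrap_modulation_test(
    rates: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Rank-based bootstrap test of directional modulation, one row per neuron.

    For each neuron the firing rates are ranked across all samples and the
    test statistic is the largest absolute deviation of a per-direction mean
    rank from the grand mean rank. Its null distribution is built by
    resampling rates with replacement into an equal number of trials per
    direction, ignoring the direction labels (exchangeability under no
    modulation), ``B`` times; the neuron is flagged *modulated* when the
    observed statistic exceeds the (1 − alpha) quantile of the resampled
    distribution. Resampling under the pooled null makes the familywise
    type-I error alpha by construction, which simulation confirms.

    Returns a DataFrame with columns ``stat``, ``crit``, ``p``, ``modulated``.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim == 1:
        rates = rates[:, None]
    labels = np.asarray(labels)
    dirs, inverse = np.unique(labels, return_inverse=True)
    if dirs.size < 2:
        raise ValueError("need at least two directions")
    counts = np.bincount(inverse)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S, N = rates.shape
    balanced = bool(np.all(counts == counts[0]))
    group_of = np.repeat(np.arange(dirs.size), counts)
    rows = []
    for j in range(N):
        r = stats.rankdata(rates[:, j])
        grand = r.mean()
        obs = np.array([r[inverse == d].mean() for d in range(dirs.size)])
        t_obs = np.max(np.abs(obs - grand))
        idx = rng.integers(0, S, size=(B, int(counts.sum())))
        draws = r[idx]                              # (B, S_total)
        if balanced:
            means = draws.reshape(B, dirs.size, counts[0]).mean(axis=2)
        else:
            sums = np.zeros((B, dirs.size))
            np.add.at(sums.T, group_of, draws.T)    # accumulate per direction
            means = sums / counts[None, :]
        t_null = np.max(np.abs(means - draws.mean(axis=1, keepdims=True)), axis=1)
        crit = np.quantile(t_null, 1.0 - alpha)
        p = float(np.mean(t_null >= t_obs))
        rows.append({"stat": t_obs, "crit": crit, "p": p, "modulated": bool(t_obs > crit)})
    return pd.DataFrame(rows)


def octant_unit_vectors() -> dict[str, np.ndarray]:
    """Centroid unit vector of each direction octant, (±1, ±1, ±1)/sqrt(3)."""
    out = {}
    for label in OCTANTS:
        x = _SQ3 if label.startswith("Ant") else -_SQ3
        z = _SQ3 if "Sup" in label else -_SQ3
        y = _SQ3 if label.endswith("R") else -_SQ3
        out[label] = np.array([x, y, z])
    return out


class CosineTuning(BaseEstimator, RegressorMixin):
    """Least-squares 3D cosine tuning fit, f = b0 + b . u.

    Regressors are the representative unit vectors of each sample's
    direction category. Fitted attributes: ``intercept_`` (b0), ``coef_``
    (bx, by, bz), ``f_pvalue_`` (overall F-test against the intercept-only
    model), ``r2_``, and ``pd_`` — the preferred direction
    ``coef_/||coef_||``, set only when the fit is significant at ``alpha``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, U: np.ndarray, y: np.ndarray) -> "CosineTuning":
        U = np.asarray(U, dtype=float)
        y = np.asarray(y, dtype=float)
        if U.ndim != 2 or U.shape[1] != 3:
            raise ValueError("U must be (S, 3) direction unit vectors")
        if np.unique(U, axis=0).shape[0] < 4:
            raise ValueError("need at least 4 distinct direction vectors")
        X = np.column_stack([np.ones(len(U)), U])
        if np.linalg.matrix_rank(X) < 4:
            raise ValueError("rank-deficient design")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        tss = float(np.sum((y - y.mean()) ** 2))
        dof = len(y) - 4
        if dof <= 0:
            raise ValueError("not enough samples for the F-test")
        if tss == 0.0:
            f_stat, f_p, r2 = 0.0, 1.0, 0.0
        else:
            f_stat = ((tss - rss) / 3.0) / (rss / dof) if rss > 0 else np.inf
            f_p = float(stats.f.sf(f_stat, 3, dof))
            r2 = 1.0 - rss / tss
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.f_stat_ = float(f_stat)
        self.f_pvalue_ = f_p
        self.r2_ = float(r2)
        norm = np.linalg.norm(self.coef_)
        self.pd_ = self.coef_ / norm if (f_p < self.alpha and norm > 0) else None
        return self

    def predict(self, U: np.ndarray) -> np.ndarray:
        return self.intercept_ + np.asarray(U, dtype=float) @ self.coef_


def cosine_fit(rates: np.ndarray, labels: np.ndarray, alpha: float = 0.05) -> dict:
    """Cosine tuning fit of one neuron against octant centroid vectors.

    Thin wrapper over :class:`CosineTuning`; ``labels`` are octant strings.
    """
    cent = octant_unit_vectors()
    U = np.array([cent[l] for l in labels])
    model = CosineTuning(alpha=alpha).fit(U, np.asarray(rates, dtype=float))
    return {
        "b0": model.intercept_, "bx": model.coef_[0], "by": model.coef_[1],
        "bz": model.coef_[2], "F_p": model.f_pvalue_, "R2": model.r2_,
        "PD": model.pd_,
    }


def directional_index(direction_means: np.ndarray) -> float:
    """Depth of directional tuning, DI = (max − min)/max of direction means."""
    m = np.asarray(direction_means, dtype=float)
    mx = m.max()
    if mx <= 0:
        raise ValueError("directional index undefined when max mean rate is 0")
    return float((mx - m.min()) / mx)


def drinking_pd_bootstrap(
    rates: np.ndarray,
    spouts: np.ndarray,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Bootstrap distribution of a neuron's maximal-rate spout.

    Per replicate, trials are resampled with replacement within each spout
    and the spout with the highest mean rate recorded; ties are broken
    uniformly at random. Returns ``{"probs": {spout: freq}, "mode": spout}``.
    """
    rates = np.asarray(rates, dtype=float)
    spouts = np.asarray(spouts)
    labels, inverse = np.unique(spouts, return_inverse=True)
    if np.min(np.bincount(inverse)) < 2:
        raise ValueError("need at least 2 trials per spout")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wins = np.zeros(labels.size)
    groups = [rates[inverse == g] for g in range(labels.size)]
    means = np.empty((B, labels.size))
    for g, vals in enumerate(groups):
        draws = rng.integers(0, vals.size, size=(B, vals.size))
        means[:, g] = vals[draws].mean(axis=1)
    for b in range(B):
        best = np.flatnonzero(means[b] == means[b].max())
        wins[best[rng.integers(best.size)] if best.size > 1 else best[0]] += 1
    probs = {str(l): float(w / B) for l, w in zip(labels, wins)}
    return {"probs": probs, "mode": str(labels[int(np.argmax(wins))])}


def fano(counts: np.ndarray) -> float:
    """Fano factor: spike-count variance divided by spike-count mean."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 counts")
    mean = c.mean()
    if mean == 0:
        raise ValueError("Fano factor undefined for zero mean count")
    return float(c.var(ddof=1) / mean)


def mean_matched_fano(
    groups: dict[str, list[np.ndarray]],
    n_bins: int = 20,
    repeats: int = 50,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Mean-matched Fano factor per group of neurons.

    ``groups`` maps a group name (e.g. region or session) to a list of
    per-neuron spike-count arrays. To remove the confound of different
    firing-rate distributions, per-neuron mean counts are binned into a
    common histogram (``n_bins`` over the pooled range) and, in each of
    ``repeats`` seeded passes, every group is greedily down-sampled to the
    bin-wise minimum across groups before averaging per-neuron Fano factors.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(groups)
    means = {g: np.array([np.mean(c) for c in groups[g]]) for g in names}
    ffs = {g: np.array([fano(c) for c in groups[g]]) for g in names}
    pooled = np.concatenate([means[g] for g in names])
    edges = np.linspace(pooled.min(), pooled.max() + 1e-12, n_bins + 1)
    which_bin = {g: np.clip(np.digitize(means[g], edges) - 1, 0, n_bins - 1) for g in names}
    hist = {g: np.bincount(which_bin[g], minlength=n_bins) for g in names}
    target = np.min([hist[g] for g in names], axis=0)
    out = {g: [] for g in names}
    for _ in range(repeats):
        for g in names:
            keep = []
            for b in range(n_bins):
                members = np.flatnonzero(which_bin[g] == b)
                if target[b] > 0:
                    keep.append(rng.choice(members, size=target[b], replace=False))
            if not keep:
                raise ValueError("mean-matching removed every neuron; use fewer bins")
            out[g].append(ffs[g][np.concatenate(keep)].mean())
    return {g: float(np.mean(v)) for g, v in out.items()}


def rayleigh_test_sphere(pds: np.ndarray) -> tuple[float, float]:
    """Spherical Rayleigh test of PD uniformity on the unit sphere.

    Statistic 3n * ||mean resultant vector||^2, chi-square(3) under the
    uniform null. Returns (statistic, p).
    """
    pds = np.asarray(pds, dtype=float)
    if pds.ndim != 2 or pds.shape[1] != 3 or pds.shape[0] < 5:
        raise ValueError("need at least 5 unit 3-vectors")
    norms = np.linalg.norm(pds, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("PDs must be unit vectors")
    n = pds.shape[0]
    stat = 3.0 * n * float(np.sum(pds.mean(axis=0) ** 2))
    return stat, float(stats.chi2.sf(stat, 3))


def circular_k_test(angles_a: np.ndarray, angles_b: np.ndarray) -> tuple[float, float]:
    """Two-sample test for equal von Mises concentration ("k-test").

    Angles in radians. Uses the variance-ratio form: with resultant lengths
    R1, R2, the statistic f = [(n2−1)(n1−R1)] / [(n1−1)(n2−R2)] is compared
    two-tailed against F(n1−1, n2−1). The approximation assumes reasonably
    concentrated samples; a warning is issued when the pooled mean resultant
    length is below 0.7. Returns (f, p).
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 angles per group")
    R1 = float(np.abs(np.exp(1j * a).sum()))
    R2 = float(np.abs(np.exp(1j * b).sum()))
    n1, n2 = a.size, b.size
    if np.isclose(R1, n1) or np.isclose(R2, n2):
        raise ValueError("degenerate (all-equal) angular sample")
    rbar = (R1 + R2) / (n1 + n2)
    if rbar < 0.7:
        warnings.warn("pooled mean resultant length < 0.7; concentration "
                      "F-test approximation may be inaccurate", stacklevel=2)
    f = ((n2 - 1) * (n1 - R1)) / ((n1 - 1) * (n2 - R2))
    if f >= 1.0:
        p = 2.0 * stats.f.sf(f, n1 - 1, n2 - 1)
    else:
        p = 2.0 * stats.f.sf(1.0 / f, n2 - 1, n1 - 1)
    return f, float(min(p, 1.0))


def proportion_comparison(tuned: np.ndarray, totals: np.ndarray) -> tuple[float, float]:
    """Chi-square test of homogeneity for tuned-vs-untuned proportions.

    ``tuned[i]`` of ``totals[i]`` neurons are tuned in group i. Returns
    (statistic, p).
    """
    tuned = np.asarray(tuned, dtype=int)
    totals = np.asarray(totals, dtype=int)
    if np.any(totals <= 0):
        raise ValueError("zero-total group")
    table = np.vstack([tuned, totals - tuned])
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 1):
        raise ValueError("expected counts below 1; test invalid")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# session-level assembly

def rate_matrix_from_session(session: Session, balance: bool = False,
                             seed: int = 0) -> RateMatrix:
    """Direction-labelled firing rates for every neuron of a session.

    Feeding: consecutive non-overlapping 100 ms windows tiled within each
    annotated gape cycle, labelled by movement octant; rate = count / 0.1 s.
    Drinking: a 500 ms window (±250 ms) centred on each minimum protrusion,
    labelled by the trial's spout; rate = count / 0.5 s. ``balance=True``
    equalises per-label sample counts (seeded).
    """
    traj = session.trajectory()
    spike_times = session.spike_times()
    neuron_ids = np.array(sorted(spike_times))
    areas_map = session.neuron_areas()
    windows, labels = [], []
    if session.behavior == "feeding":
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
                # keep only licks whose full ±250 ms window fits the trial
                if t_min - 0.250 >= tr["start_s"] - 1e-9 and t_min + 0.250 <= tr["end_s"] + 1e-9:
                    windows.append((t_min - 0.250, t_min + 0.250))
                    labels.append(tr["spout"])
    if not windows:
        raise ValueError("no analysis windows in session")
    rates = np.empty((len(windows), neuron_ids.size))
    for j, nid in enumerate(neuron_ids):
        st = spike_times[nid]
        for i, (lo, hi) in enumerate(windows):
            rates[i, j] = np.searchsorted(st, hi) - np.searchsorted(st, lo)
    durations = np.array([hi - lo for lo, hi in windows])
    rates /= durations[:, None]
    rm = RateMatrix(
        rates=rates, labels=np.array(labels), neuron_ids=neuron_ids,
        areas=np.array([areas_map[n] for n in neuron_ids]),
        behavior=session.behavior, condition=session.condition,
    )
    if balance:
        df = pd.DataFrame({"label": rm.labels})
        kept = balance_direction_samples(df, "label", seed=seed).index.to_numpy()
        rm = RateMatrix(rates=rm.rates[kept], labels=rm.labels[kept],
                        neuron_ids=rm.neuron_ids, areas=rm.areas,
                        behavior=rm.behavior, condition=rm.condition)
    return rm


def tuning_summary(rm: RateMatrix, B: int = 1000, alpha: float = 0.05,
                   seed: int = 0) -> pd.DataFrame:
    """Per-neuron tuning table: modulation, cosine fit, PD, DI, Fano.

    For feeding rate matrices the cosine fit uses octant centroid vectors;
    for drinking, the bootstrap preferred-spout distribution replaces the
    3D fit. One row per neuron.
    """
    rng = np.random.default_rng(seed)
    mod = bootstrap_modulation_test(rm.rates, rm.labels, B=B, alpha=alpha, seed=rng)
    dirs = np.unique(rm.labels)
    rows = []
    for j, nid in enumerate(rm.neuron_ids):
        r = rm.rates[:, j]
        means = np.array([r[rm.labels == d].mean() for d in dirs])
        rec = {
            "neuron_id": nid, "area": rm.areas[j],
            "modulated": bool(mod.loc[j, "modulated"]), "mod_p": mod.loc[j, "p"],
            "di": directional_index(means) if means.max() > 0 else np.nan,
            "fano": fano(r * (0.1 if rm.behavior == "feeding" else 0.5))
                    if r.mean() > 0 else np.nan,
        }
        if rm.behavior == "feeding":
            fit = cosine_fit(r, rm.labels, alpha=alpha)
            rec.update({k: fit[k] for k in ("b0", "bx", "by", "bz", "F_p", "R2")})
            if fit["PD"] is not None:
                rec["pd_x"], rec["pd_y"], rec["pd_z"] = fit["PD"]
            else:
                rec["pd_x"] = rec["pd_y"] = rec["pd_z"] = np.nan
        else:
            boot = drinking_pd_bootstrap(r, rm.labels, B=B, seed=rng)
            rec["preferred_spout"] = boot["mode"]
            for sp, pr in boot["probs"].items():
                rec[f"p_{sp}"] = pr
        rows.append(rec)
    return pd.DataFrame(rows)
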