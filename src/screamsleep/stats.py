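"""First/second-order statistics: condition averages, single-trial
regressions on acoustic features, paired cluster-based permutation tests
and Cohen's d.

First-order statistics are computed within a participant (trial averages,
ITPC, or regression slopes), channels are averaged within participant, and
second-order inference runs across participants.  The cluster test forms
runs of consecutive time points whose paired two-tailed t-test falls below
the point-wise threshold, scores each run by the sum of its t values, and
compares the observed scores against a sign-flip permutation null of the
maximal |cluster| statistic.  Monte-Carlo p values use the +1 correction:
p = (1 + #{null >= |obs|}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "zscore_features",
    "trial_average",
    "channel_average",
    "single_trial_regression",
    "Cluster",
    "ClusterTestResult",
    "paired_cluster_permutation",
    "cohens_d",
]


def zscore_features(values) -> np.ndarray:
    """Standardize stimulus features to mean 0, sample SD 1 (n−1 denominator)."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2 or x.std(ddof=1) == 0:
        raise ValueError("cannot z-score a constant feature")
    return (x - x.mean()) / x.std(ddof=1)


def trial_average(data: np.ndarray, mask=None) -> np.ndarray:
    """Average over trials (axis 0), optionally restricted by a boolean mask."""
    if mask is not None:
        data = data[np.asarray(mask)]
    if data.shape[0] == 0:
        raise ValueError("empty trial selection")
    return data.mean(axis=0)


def channel_average(data: np.ndarray, axis: int = 0) -> np.ndarray:
    """Average over channels; applied after per-channel first-order stats."""
    return data.mean(axis=axis)


def single_trial_regression(power: np.ndarray, feature: np.ndarray,
                            feature2: np.ndarray | None = None) -> np.ndarray:
    """OLS slope of power on a z-scored feature, per remaining axis element.

    ``power`` is (n_trials, ...); returns the slope array of shape
    ``power.shape[1:]``.  With ``feature2`` given, both regressors enter a
    joint OLS and the slope of ``feature`` is returned (the default is a
    simple regression; features are near-orthogonal by stimulus design).
    """
    y = np.asarray(power, dtype=float)
    z = np.asarray(feature, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trials")
    if z.std() == 0:
        raise ValueError("feature has zero variance (singular design)")
    if feature2 is None:
        zc = z - z.mean()
        yc = y - y.mean(axis=0, keepdims=True)
        return np.tensordot(zc, yc, axes=(0, 0)) / np.sum(zc**2)
    X = np.column_stack([np.ones(n), z, np.asarray(feature2, dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y.reshape(n, -1), rcond=None)
    return beta[1].reshape(y.shape[1:])


@dataclass
class Cluster:
    """A contiguous supra-threshold run with its summed-t statistic."""

    start: int  # index into the analysis window
    stop: int  # exclusive
    start_s: float
    stop_s: float
    stat: float  # sum of t values (t_cluster)
    p: float  # Monte-Carlo p (p_cluster)
    sign: int
    mean: float  # cluster-averaged difference, mean across participants
    sd: float
    d: float  # Cohen's d of the cluster-averaged values

    def to_dict(self) -> dict:
        return {
            "start_s": self.start_s, "stop_s": self.stop_s, "t_cluster": self.stat,
            "p_cluster": self.p, "sign": self.sign, "mean": self.mean,
            "sd": self.sd, "cohens_d": self.d,
        }


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    window: tuple[float, float]
    n_participants: int
    n_perm: int
    alpha_point: float
    seed: int | None = None
    times: np.ndarray | None = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_dict(self) -> dict:
        return {
            "window_s": list(self.window),
            "n_participants": self.n_participants,
            "n_perm": self.n_perm,
            "alpha_point": self.alpha_point,
            "seed": self.seed,
            "clusters": [c.to_dict() for c in self.clusters],
        }


def _runs(mask: np.ndarray):
    """Contiguous True runs of a boolean vector as (start, stop) pairs."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return zip(starts, stops)


def _max_run_sums(vals: np.ndarray) -> np.ndarray:
    """Per row, the maximal sum over contiguous runs of positive entries.

    ``vals`` is (n_perm, n_time) with zeros breaking runs.  Uses the
    cumulative-sum-with-reset identity: a run ending at j sums to
    c[j] − c[last zero ≤ j], and c is nondecreasing for nonnegative vals.
    """
    c = np.cumsum(vals, axis=1)
    at_zero = np.where(vals == 0, c, 0.0)
    last_zero_c = np.maximum.accumulate(at_zero, axis=1)
    run_sums = np.where(vals > 0, c - last_zero_c, 0.0)
    return run_sums.max(axis=1)


def _t_onesample(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return m / (sd / np.sqrt(n))


def paired_cluster_permutation(a: np.ndarray, b: np.ndarray | float | None, times: np.ndarray,
                               window: tuple[float, float] | None = None,
                               alpha_point: float = 0.05, n_perm: int = 5000,
                               seed: int | None = None,
                               rng: np.random.Generator | None = None) -> ClusterTestResult:
    """Cluster-based sign-flip permutation test on participants × time series.

    ``a`` minus ``b`` (``b`` may be 0/None for a test against baseline) is
    tested point-wise with a paired two-tailed t-test at ``alpha_point``;
    contiguous supra-threshold runs of one sign form clusters scored by
    their summed t.  The null distribution is the maximal |cluster| score
    over random per-participant sign flips of the differences.  Clusters of
    either sign are reported with p, cluster-averaged mean difference, SD
    across participants and Cohen's d, significant or not.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if b is None:
        d = a
    else:
        b_arr = np.asarray(b, dtype=float)
        d = a - (b_arr if b_arr.ndim else float(b_arr))
    n_p, n_t = d.shape
    if n_p < 5:
        raise ValueError("need at least 5 participants")
    times = np.asarray(times, dtype=float)
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
        d = d[:, sel]
        times = times[sel]
    else:
        window = (float(times[0]), float(times[-1]))
    if d.shape[1] == 0:
        raise ValueError("analysis window contains no samples")
    sd0 = d.std(axis=0, ddof=1) == 0
    if np.any(sd0 & (d.mean(axis=0) != 0)):
        raise ValueError("degenerate (zero-variance, nonzero-mean) differences")

    t_obs = _t_onesample(d)
    t_obs[sd0] = 0.0  # identical pairs carry no evidence
    t_crit = sstats.t.ppf(1.0 - alpha_point / 2.0, df=n_p - 1)

    if rng is None:
        rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_p))
    # t under sign flips, from sufficient statistics: Σ s_i d_i and Σ d_i²
    m_perm = signs @ d / n_p
    ssq = np.sum(d**2, axis=0)
    var_perm = (ssq[None, :] - n_p * m_perm**2) / (n_p - 1)
    var_perm = np.maximum(var_perm, np.finfo(float).tiny)
    t_perm = m_perm / np.sqrt(var_perm / n_p)

    pos = np.where(t_perm > t_crit, t_perm, 0.0)
    neg = np.where(-t_perm > t_crit, -t_perm, 0.0)
    null = np.maximum(_max_run_sums(pos), _max_run_sums(neg))

    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t_obs) > t_crit
        for start, stop in _runs(mask):
            stat = float(t_obs[start:stop].sum())
            # tolerance absorbs last-ulp differences between the observed
            # statistic and its own (identity) permutation
            thresh = abs(stat) * (1.0 - 1e-9)
            p = float((1 + np.sum(null >= thresh)) / (1 + n_perm))
            cluster_vals = d[:, start:stop].mean(axis=1)
            mean = float(cluster_vals.mean())
            sd = float(cluster_vals.std(ddof=1))
            clusters.append(
                Cluster(
                    start=int(start), stop=int(stop),
                    start_s=float(times[start]), stop_s=float(times[stop - 1]),
                    stat=stat, p=p, sign=sign, mean=mean, sd=sd,
                    d=mean / sd if sd > 0 else float("nan"),
                )
            )
    clusters.sort(key=lambda c: c.p)
    return ClusterTestResult(
        clusters=clusters, window=window, n_participants=n_p, n_perm=n_perm,
        alpha_point=alpha_point, seed=seed, times=times,
    )


def cohens_d(values) -> float:
    """Effect size d = mean / sample SD of participant-level values."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero standard deviation")
    return float(x.mean() / s)
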