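"""Group-level inference on TRF timecourses.

Implements the paired temporal cluster-based permutation test used to
compare channel-averaged TRF curves between conditions (cluster-forming
|t| threshold, cluster mass = summed t, sign-flip permutation null of the
maximal cluster mass), Gaussian smoothing of single-subject beta
timecourses, and across-subject Spearman correlations between beta
timecourses and behavioural parameters (e.g. kernel decay constants).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import spearmanr

__all__ = [
    "Cluster",
    "ClusterResult",
    "CorrelationTimecourse",
    "smooth_timecourse",
    "paired_cluster_permutation",
    "across_subject_correlation",
]


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    mass: float  # summed t-statistic over the cluster
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    times_ms: np.ndarray
    threshold_t: float
    n_permutations: int
    alpha: float

    def significant_clusters(self, alpha: float | None = None) -> list[Cluster]:
        a = self.alpha if alpha is None else alpha
        return [c for c in self.clusters if c.p_value < a]


@dataclass
class CorrelationTimecourse:
    times_ms: np.ndarray
    rho: np.ndarray
    window_ms: tuple[float, float]
    window_mean_rho: float
    n_subjects: int


def gaussian_kernel(fwhm_ms: float, fs_hz: float) -> np.ndarray:
    """Unit-area Gaussian kernel with the given FWHM, truncated at 4 SD."""
    sd = fwhm_ms / (2.0 * math.sqrt(2.0 * math.log(2.0))) * fs_hz / 1000.0
    radius = max(1, int(math.ceil(4.0 * sd)))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def smooth_timecourse(
    betas: np.ndarray, fwhm_ms: float = 75.0, fs_hz: float = 100.0
) -> np.ndarray:
    """Gaussian-smooth a beta timecourse (last axis) with reflective edges."""
    if fwhm_ms <= 0:
        raise ValueError("fwhm_ms must be positive")
    betas = np.asarray(betas, dtype=float)
    k = gaussian_kernel(fwhm_ms, fs_hz)
    radius = (len(k) - 1) // 2
    def _smooth1d(x):
        xp = np.pad(x, radius, mode="symmetric")
        return np.convolve(xp, k, mode="valid")
    return np.apply_along_axis(_smooth1d, -1, betas)


@njit(cache=False)
def _max_cluster_mass(t: np.ndarray, thr: float) -> float:
    """Largest |summed t| over contiguous runs with |t| > thr."""
    best = 0.0
    acc = 0.0
    in_run = False
    for i in range(t.shape[0]):
        if abs(t[i]) > thr:
            if not in_run:
                acc = 0.0
                in_run = True
            acc += t[i]
            if abs(acc) > best:
                best = abs(acc)
        else:
            in_run = False
    return best


def _clusters_from_t(t: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """(start, stop_exclusive, mass) for runs of |t| > thr.

    Runs are split where the sign of t changes, so each cluster carries a
    consistent sign.
    """
    out = []
    i = 0
    n = len(t)
    while i < n:
        if abs(t[i]) > thr:
            sign = 1.0 if t[i] > 0 else -1.0
            j = i
            while j < n and abs(t[j]) > thr and (t[j] > 0) == (sign > 0):
                j += 1
            out.append((i, j, float(t[i:j].sum())))
            i = j
        else:
            i += 1
    return out


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def paired_cluster_permutation(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times_ms: np.ndarray | None = None,
    threshold_t: float = 2.07,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> ClusterResult:
    """Paired cluster-based permutation test on per-subject timecourses.

    ``cond_a``/``cond_b`` are (n_subjects, n_times) channel-averaged
    curves.  Per-timepoint paired t-statistics form clusters where
    |t| > ``threshold_t`` (split at sign changes); each cluster is scored
    by its summed t.  The null distribution of the maximal |cluster mass|
    is built from random sign flips of the subject difference curves
    (full enumeration when 2^n ≤ n_perm), with the observed labelling
    included, so p ≥ 1/n_perm.  Two-tailed by construction.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need matching (n_subjects>=2, n_times) arrays")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse p-values", RuntimeWarning)
    n_sub, n_time = a.shape
    if times_ms is None:
        times_ms = np.arange(n_time, dtype=float)
    diffs = a - b
    t_obs = _paired_t(diffs)
    raw = _clusters_from_t(t_obs, threshold_t)

    if 2 ** n_sub <= n_perm:
        n_eff = 2 ** n_sub
        signs = np.array(
            [[1 if (m >> s) & 1 == 0 else -1 for s in range(n_sub)]
             for m in range(n_eff)],
            dtype=float,
        )
    else:
        n_eff = n_perm
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_eff, n_sub))
        signs[0, :] = 1.0  # observed labelling included in the null

    null_max = np.empty(n_eff)
    for p in range(n_eff):
        t_p = _paired_t(signs[p][:, None] * diffs)
        null_max[p] = _max_cluster_mass(t_p, threshold_t)

    clusters = []
    for i, j, mass in raw:
        pval = float(np.mean(null_max >= abs(mass)))
        clusters.append(
            Cluster(
                start_ms=float(times_ms[i]),
                end_ms=float(times_ms[j - 1]),
                mass=mass,
                p_value=pval,
            )
        )
    return ClusterResult(
        clusters=clusters,
        t_values=t_obs,
        times_ms=np.asarray(times_ms, dtype=float),
        threshold_t=threshold_t,
        n_permutations=n_eff,
        alpha=alpha,
    )


def across_subject_correlation(
    beta_curves: np.ndarray,
    behav_values: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float] = (420.0, 750.0),
) -> CorrelationTimecourse:
    """Spearman correlation between per-subject betas and a behavioural value.

    ``beta_curves`` is (n_subjects, n_times) — typically smoothed with
    :func:`smooth_timecourse` first; ``behav_values`` one value per
    subject (e.g. the kernel decay constant tau).  ``window_mean_rho``
    correlates the window-averaged betas against the behavioural values.
    Ties are handled by average ranks; a constant input yields NaN.
    """
    B = np.asarray(beta_curves, dtype=float)
    v = np.asarray(behav_values, dtype=float)
    if B.ndim != 2 or B.shape[0] != v.shape[0]:
        raise ValueError("need one curve and one value per subject")
    if B.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    times_ms = np.asarray(times_ms, dtype=float)
    rho = np.empty(B.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ti in range(B.shape[1]):
            rho[ti] = spearmanr(B[:, ti], v).statistic
        lo, hi = window_ms
        sel = (times_ms >= lo) & (times_ms <= hi)
        wmean = spearmanr(B[:, sel].mean(axis=1), v).statistic if sel.any() else np.nan
    return CorrelationTimecourse(
        times_ms=times_ms,
        rho=rho,
        window_ms=(float(lo), float(hi)),
        window_mean_rho=float(wmean) if np.isfinite(wmean) else math.nan,
        n_subjects=B.shape[0],
    )
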