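"""Group-level statistics on ACI weight maps.

Two groups of listeners are compared bin-by-bin with a running t-test;
clusters of adjacent significant bins (4-connectivity, split by sign)
are then assessed against a permutation null built from the maximum
absolute cluster mass under random relabelings of the group membership
(the standard cluster-based correction for multiple comparisons on a
time-frequency lattice).  Regions of interest are defined on the
pooled cohort as one-sample clusters of at least 7 adjacent bins
significant at p < 1e-10, and mean ROI weights are compared between
groups with ordinary two-sample t-tests.  A two-pass "individual
deviance analysis" flags single participants falling beyond 1.65 SD of
a control distribution trimmed of its own >1.65 SD outliers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

#: 4-connected neighbourhood on the time-frequency lattice (no diagonals)
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


# ---------------------------------------------------------------------------
# running t-tests
# ---------------------------------------------------------------------------

def running_ttest(maps_a, maps_b=None):
    """Per-bin t statistic and two-tailed p over stacked weight maps.

    Two-sample (equal-variance pooled) when ``maps_b`` is given,
    one-sample against zero otherwise (the ROI mode).  Bins with zero
    variance get t=0, p=1 with a warning.
    """
    A = np.stack([np.asarray(m, dtype=float) for m in maps_a])
    if A.shape[0] < 2:
        raise ValueError("need at least 2 maps per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        if maps_b is None:
            res = stats.ttest_1samp(A, 0.0, axis=0)
        else:
            B = np.stack([np.asarray(m, dtype=float) for m in maps_b])
            if B.shape[0] < 2:
                raise ValueError("need at least 2 maps per group")
            if A.shape[1:] != B.shape[1:]:
                raise ValueError("group maps must share a shape")
            res = stats.ttest_ind(A, B, axis=0, equal_var=True)
    t_map = np.asarray(res.statistic, dtype=float)
    p_map = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(t_map)
    if np.any(bad):
        warnings.warn(f"{bad.sum()} zero-variance bins: t set to 0, p to 1",
                      RuntimeWarning, stacklevel=2)
        t_map[bad] = 0.0
        p_map[bad] = 1.0
    return t_map, p_map


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def find_clusters(p_map: np.ndarray, t_map: np.ndarray, alpha: float,
                  min_size: int = 1) -> list[np.ndarray]:
    """Maximal 4-connected components of {p < alpha}, split by t sign.

    Returns boolean masks (one per cluster); components smaller than
    ``min_size`` bins are dropped.  Bins touching only diagonally
    belong to different clusters.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    sig = p_map < alpha
    masks: list[np.ndarray] = []
    for sign_mask in (sig & (t_map > 0), sig & (t_map < 0)):
        labels, n = ndimage.label(sign_mask, structure=FOUR_CONN)
        for k in range(1, n + 1):
            m = labels == k
            if m.sum() >= min_size:
                masks.append(m)
    return masks


@dataclass
class ClusterTestResult:
    """Observed clusters with permutation p-values."""

    t_map: np.ndarray
    clusters: list[np.ndarray]              # boolean masks
    cluster_stat: np.ndarray                # signed sum of t per cluster
    p_values: np.ndarray
    n_permutations: int
    cluster_alpha: float
    null_max_stat: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": np.arange(1, len(self.clusters) + 1),
            "size": [int(m.sum()) for m in self.clusters],
            "stat": self.cluster_stat,
            "p": self.p_values,
        })


def _max_cluster_stat(t_map: np.ndarray, p_map: np.ndarray,
                      alpha: float) -> float:
    masks = find_clusters(p_map, t_map, alpha)
    if not masks:
        return 0.0
    return max(abs(float(t_map[m].sum())) for m in masks)


def _two_sample_t(pooled: np.ndarray, idx_a: np.ndarray,
                  idx_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fast equal-variance t over the first axis for one label split."""
    na, nb = len(idx_a), len(idx_b)
    A, B = pooled[idx_a], pooled[idx_b]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[~np.isfinite(t)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=na + nb - 2)
    return t, p


def cluster_permutation_test(maps_a, maps_b, n_perm: int = 5000,
                             alpha: float = 0.05, seed: int = 0
                             ) -> ClusterTestResult:
    """Cluster-based permutation test between two groups of maps.

    Observed clusters come from the running t-test thresholded at the
    per-bin ``alpha`` (two-tailed); the null distribution is the
    maximum absolute cluster mass (sum of t within a cluster) over
    ``n_perm`` random permutations of the group labels, and each
    observed cluster gets ``p = (1 + #{null >= |stat|}) / (n_perm + 1)``.
    When the number of distinct label splits does not exceed
    ``n_perm``, all splits are enumerated instead and p-values are
    exact proportions over the full permutation distribution.
    """
    A = np.stack([np.asarray(m, dtype=float) for m in maps_a])
    B = np.stack([np.asarray(m, dtype=float) for m in maps_b])
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 maps per group")
    na, nb = A.shape[0], B.shape[0]
    pooled = np.concatenate([A, B]).reshape(na + nb, -1)
    shape = A.shape[1:]
    idx_a0 = np.arange(na)
    idx_b0 = np.arange(na, na + nb)
    t_obs_flat, p_obs = _two_sample_t(pooled, idx_a0, idx_b0)
    t_obs = t_obs_flat.reshape(shape)
    clusters = find_clusters(p_obs.reshape(shape), t_obs, alpha)
    stat_obs = np.array([float(t_obs[m].sum()) for m in clusters])

    from math import comb
    n_splits = comb(na + nb, na)
    exhaustive = n_splits <= n_perm
    if exhaustive:
        splits = itertools.combinations(range(na + nb), na)
        n_used = n_splits
    else:
        rng = np.random.default_rng(seed)
        splits = (rng.permutation(na + nb)[:na] for _ in range(n_perm))
        n_used = n_perm
    null = np.empty(n_used)
    all_idx = np.arange(na + nb)
    for i, sa in enumerate(splits):
        ia = np.fromiter(sa, dtype=int) if exhaustive else np.sort(sa)
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        t_p, p_p = _two_sample_t(pooled, ia, ib)
        null[i] = _max_cluster_stat(t_p.reshape(shape),
                                    p_p.reshape(shape), alpha)
    if exhaustive:
        p_vals = np.array([(null >= abs(s)).sum() / n_used
                           for s in stat_obs])
    else:
        p_vals = np.array([(1.0 + (null >= abs(s)).sum()) / (n_used + 1.0)
                           for s in stat_obs])
    return ClusterTestResult(t_map=t_obs, clusters=clusters,
                             cluster_stat=stat_obs, p_values=p_vals,
                             n_permutations=n_used, cluster_alpha=alpha,
                             null_max_stat=null)


# ---------------------------------------------------------------------------
# regions of interest
# ---------------------------------------------------------------------------

@dataclass
class ROISet:
    """Consistently-weighted regions on the pooled cohort maps."""

    masks: list[np.ndarray]
    polarity: np.ndarray                  # +1 'da'-positive, -1 'ga'-negative
    sizes: np.ndarray
    centroids: list[tuple[float, float]]  # (time ms, frequency Hz)

    def __len__(self) -> int:
        return len(self.masks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi": np.arange(1, len(self.masks) + 1),
            "size": self.sizes,
            "polarity": self.polarity,
            "centroid_t_ms": [c[0] for c in self.centroids],
            "centroid_f_hz": [c[1] for c in self.centroids],
        })


def define_rois(maps_all, alpha: float = 1e-10, min_size: int = 7,
                frame_times: np.ndarray | None = None,
                center_frequencies: np.ndarray | None = None) -> ROISet:
    """ROIs: one-sample running t-test on the pooled maps, 4-connected
    components of {p < alpha} with at least ``min_size`` bins.

    Centroids are weight-magnitude-weighted means of the frame times
    and channel center frequencies (bin indices when axes are not
    given).  An empty ROISet is a valid result.
    """
    maps = [np.asarray(m, dtype=float) for m in maps_all]
    if len(maps) < 3:
        raise ValueError("need at least 3 maps to define ROIs")
    t_map, p_map = running_ttest(maps)
    masks = find_clusters(p_map, t_map, alpha, min_size=min_size)
    mean_map = np.mean(maps, axis=0)
    nf, nt = mean_map.shape
    ft = np.asarray(frame_times) if frame_times is not None \
        else np.arange(nt, dtype=float)
    cf = np.asarray(center_frequencies) if center_frequencies is not None \
        else np.arange(nf, dtype=float)
    polarity, sizes, centroids = [], [], []
    for m in masks:
        w = np.abs(mean_map[m])
        ch_idx, fr_idx = np.nonzero(m)
        centroids.append((float(np.average(ft[fr_idx], weights=w)),
                          float(np.average(cf[ch_idx], weights=w))))
        polarity.append(1 if mean_map[m].mean() > 0 else -1)
        sizes.append(int(m.sum()))
    return ROISet(masks=masks, polarity=np.array(polarity, dtype=int),
                  sizes=np.array(sizes, dtype=int), centroids=centroids)


def roi_compare(rois: ROISet, maps_a, maps_b) -> pd.DataFrame:
    """Two-sample t-test of mean ROI weights between groups.

    Per observer, beta is averaged over the ROI bins; the per-ROI group
    means are compared with an equal-variance t-test.  Returns one row
    per ROI: mean_a, mean_b, t, p.
    """
    if len(rois) == 0:
        raise ValueError("empty ROI set")
    A = np.stack([np.asarray(m, dtype=float) for m in maps_a])
    B = np.stack([np.asarray(m, dtype=float) for m in maps_b])
    rows = []
    for i, mask in enumerate(rois.masks):
        if not mask.any():
            raise ValueError(f"ROI {i + 1} is empty")
        a = A[:, mask].mean(axis=1)
        b = B[:, mask].mean(axis=1)
        if np.allclose(a, b) and np.allclose(a.var(), b.var()):
            t, p = (0.0, 1.0) if np.allclose(a.mean(), b.mean()) else \
                stats.ttest_ind(a, b, equal_var=True)
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"roi": i + 1, "size": int(mask.sum()),
                     "polarity": int(rois.polarity[i]),
                     "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
                     "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
                     "t": t, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# individual deviance analysis
# ---------------------------------------------------------------------------

def individual_deviance_analysis(control_scores, case_scores,
                                 direction: str = "both",
                                 z_threshold: float = 1.65):
    """Two-pass outlier flagging against a trimmed control distribution.

    Pass 1 computes the control mean and SD and removes controls beyond
    ``z_threshold`` (1.65 SD, the 5th percentile of the normal); pass 2
    recomputes mean/SD on the trimmed controls and flags each case
    beyond the threshold.  ``direction`` declares which tail counts as
    deviant: 'low' (lower-is-worse), 'high', or 'both'.

    Returns a boolean array, one flag per case.  Controls with zero
    initial SD are degenerate and raise; if trimming collapses the SD
    to zero, a case is deviant iff it differs from the trimmed mean.
    """
    c = np.asarray(control_scores, dtype=float)
    x = np.atleast_1d(np.asarray(case_scores, dtype=float))
    if c.size < 3:
        raise ValueError("need at least 3 control scores")
    if direction not in ("low", "high", "both"):
        raise ValueError("direction must be 'low', 'high' or 'both'")
    mu, sd = c.mean(), c.std(ddof=1)
    if sd == 0.0:
        raise ValueError("control scores have zero standard deviation")
    keep = np.abs(c - mu) <= z_threshold * sd
    trimmed = c[keep]
    mu2, sd2 = trimmed.mean(), trimmed.std(ddof=1)
    if sd2 == 0.0:
        with np.errstate(invalid="ignore"):
            z = np.where(x == mu2, 0.0, np.inf * np.sign(x - mu2))
    else:
        z = (x - mu2) / sd2
    if direction == "low":
        return z < -z_threshold
    if direction == "high":
        return z > z_threshold
    return np.abs(z) > z_threshold
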