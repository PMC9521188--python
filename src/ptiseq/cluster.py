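"""Z-scored trajectory clustering of DEG time profiles.

DEG expression profiles (replicate-averaged, normalized) are standardized
per gene to mean 0 / sd 1 across time points, clustered with Euclidean
k-means (k = 10 in the flg22 study), and the number of clusters is
assessed with the gap statistic of Tibshirani, Walther & Hastie (uniform
reference over per-feature ranges).

Cluster labels are re-ordered deterministically by (direction, extremum
time): down-regulated clusters first, ordered by trough time, then
up-regulated clusters by peak time — mirroring the conventional 1..k
presentation with down clusters on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


# ---------------------------------------------------------------------------
# z-scaling
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryMatrix:
    """Per-gene z-scored time profiles.

    ``z`` rows have mean 0 and sample sd 1 (n-1 denominator); genes whose
    raw profile had zero variance are excluded and listed in ``flagged``.
    """

    gene_ids: list
    timepoints_h: list
    z: np.ndarray
    flagged: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.gene_ids, columns=self.timepoints_h)


def zscale(profiles: pd.DataFrame) -> TrajectoryMatrix:
    """Row-standardize gene × time-point profiles.

    Uses the sample standard deviation (n-1). Constant rows are excluded
    and reported in ``flagged``; any non-finite value raises, naming the
    gene.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 time points to z-scale")
    x = profiles.to_numpy(float)
    bad = ~np.isfinite(x)
    if bad.any():
        g = profiles.index[np.argwhere(bad)[0][0]]
        raise ValueError(f"non-finite profile value for gene {g!r}")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    z = (x[keep] - mean[keep]) / sd[keep]
    return TrajectoryMatrix(
        gene_ids=list(profiles.index[keep]),
        timepoints_h=list(profiles.columns),
        z=z,
        flagged=list(profiles.index[~keep]),
    )


def replicate_mean_profiles(counts, factors, log2: bool = True) -> pd.DataFrame:
    """Per-time-point mean of normalized expression over the replicates.

    Counts are corrected by effective size factors (library size × TMM
    factor, geometric-mean centered) and, by default, log2(x+1)
    transformed before averaging, so that up- and down-regulation deviate
    symmetrically from baseline in the z-scored profiles.
    """
    eff = counts.lib_sizes().astype(float) * factors[counts.counts.columns]
    eff = eff / np.exp(np.mean(np.log(eff)))
    norm = counts.counts.div(eff, axis=1)
    if log2:
        norm = np.log2(norm + 1.0)
    tps = counts.timepoints
    cols = {}
    for t in tps:
        sel = counts.samples.index[counts.samples["timepoint_h"].astype(float) == float(t)]
        cols[float(t)] = norm[sel].mean(axis=1)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# k-means model / results
# ---------------------------------------------------------------------------

def _direction_and_extremum(centroid: np.ndarray, timepoints) -> tuple:
    """('up'|'down', extremum time) for a baseline-anchored centroid.

    Since profiles are contrasts against the 0 h control, direction is
    judged relative to the centroid's baseline value: down iff the
    largest excursion below it exceeds the largest excursion above it
    (ties resolve to up). The extremum is the trough (down) or peak (up).
    """
    below = centroid[0] - centroid.min()
    above = centroid.max() - centroid[0]
    if below > above:
        return "down", timepoints[int(np.argmin(centroid))]
    return "up", timepoints[int(np.argmax(centroid))]


def _onset_time(centroid: np.ndarray, timepoints, direction: str) -> float:
    """First time the centroid reaches half its extremum deviation from
    baseline (tie-break for clusters peaking at the same time point)."""
    dev = centroid[0] - centroid if direction == "down" else centroid - centroid[0]
    half = 0.5 * dev.max()
    idx = int(np.argmax(dev >= half))
    return float(timepoints[idx])


class TrajectoryKMeans:
    """Euclidean k-means on a z-scored trajectory matrix.

    Parameters
    ----------
    traj : TrajectoryMatrix
    k : int
        Number of clusters (10 in the flg22 study).
    seed : int
        Seed for the careful-seeding (k-means++) initializations.
    n_restarts : int
        Independent initializations; the solution with minimal
        within-cluster sum of squares is kept.
    """

    def __init__(self, traj: TrajectoryMatrix, k: int = 10, seed: int = 0, n_restarts: int = 25):
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > traj.z.shape[0]:
            raise ValueError(f"k={k} exceeds the number of genes ({traj.z.shape[0]})")
        self.traj = traj
        self.k = int(k)
        self.seed = int(seed)
        self.n_restarts = int(n_restarts)

    def fit(self) -> "ClusterResults":
        km = KMeans(
            n_clusters=self.k,
            init="k-means++",
            n_init=self.n_restarts,
            random_state=self.seed,
        ).fit(self.traj.z)
        return ClusterResults(self.traj, km.labels_, km.cluster_centers_, float(km.inertia_))


class ClusterResults:
    """A fitted k-means partition with deterministic 1..k relabeling.

    Attributes
    ----------
    labels : pandas.Series
        gene_id -> cluster label in 1..k, down clusters (by trough time)
        before up clusters (by peak time).
    centroids : pandas.DataFrame
        k × time-points centroid matrix (index = cluster label).
    inertia : float
        Within-cluster sum of squares W_k.
    """

    def __init__(self, traj: TrajectoryMatrix, raw_labels, centers, inertia: float):
        self.traj = traj
        tps = traj.timepoints_h
        k = centers.shape[0]
        meta = []
        for c in range(k):
            direction, ext = _direction_and_extremum(centers[c], tps)
            onset = _onset_time(centers[c], tps, direction)
            meta.append((direction, ext, onset, c))
        order = sorted(
            meta,
            key=lambda m: (
                0 if m[0] == "down" else 1,
                float(m[1]),
                m[2],
                tuple(np.round(centers[m[3]], 10)),
            ),
        )
        relabel = {old: new + 1 for new, (_, _, _, old) in enumerate(order)}
        self.labels = pd.Series(
            [relabel[c] for c in raw_labels], index=traj.gene_ids, name="cluster"
        )
        self.centroids = pd.DataFrame(
            [centers[old] for _, _, _, old in order],
            index=range(1, k + 1),
            columns=tps,
        )
        self.centroids.index.name = "cluster"
        self.inertia = float(inertia)
        self.k = k

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(range(1, self.k + 1), fill_value=0)

    def summary(self) -> pd.DataFrame:
        """Per-cluster direction, extremum (peak/trough) time, and size."""
        tps = list(self.centroids.columns)
        rows = []
        for c in self.centroids.index:
            cent = self.centroids.loc[c].to_numpy()
            direction, ext = _direction_and_extremum(cent, tps)
            rows.append((c, direction, float(ext), int(self.sizes[c])))
        return pd.DataFrame(rows, columns=["cluster", "direction", "extremum_h", "size"]).set_index("cluster")

    def select_markers(
        self,
        contrasts: pd.DataFrame,
        n_per_cluster: int = 2,
        clusters=None,
        corr_floor: float = 0.8,
    ) -> pd.DataFrame:
        """Representative marker genes per cluster.

        Within each requested cluster (default: all up-regulated clusters),
        genes whose z-profile correlates with the centroid at >=
        ``corr_floor`` are ranked by maximal \\|log2FC\\| over the contrasts
        and the top ``n_per_cluster`` are returned. If no gene clears the
        floor the cluster falls back to pure correlation ranking and the
        rows are flagged.
        """
        summ = self.summary()
        if clusters is None:
            clusters = [c for c in summ.index if summ.loc[c, "direction"] == "up"]
        zf = self.traj.to_frame()
        max_fc = contrasts.dropna(subset=["log2FC"]).groupby("gene_id")["log2FC"].apply(
            lambda s: float(np.max(np.abs(s)))
        )
        rows = []
        for c in clusters:
            genes = self.labels.index[self.labels == c]
            cent = self.centroids.loc[c].to_numpy()
            cc = cent - cent.mean()
            denom_c = np.sqrt((cc**2).sum())
            recs = []
            for g in genes:
                zg = zf.loc[g].to_numpy()
                zgc = zg - zg.mean()
                denom = np.sqrt((zgc**2).sum()) * denom_c
                r = float(zgc @ cc / denom) if denom > 0 else 0.0
                recs.append((g, r, float(max_fc.get(g, 0.0))))
            passing = [x for x in recs if x[1] >= corr_floor]
            fallback = not passing
            if fallback:
                ranked = sorted(recs, key=lambda x: (-x[1], x[0]))
            else:
                ranked = sorted(passing, key=lambda x: (-x[2], -x[1], x[0]))
            for g, r, fc in ranked[:n_per_cluster]:
                rows.append((c, g, r, fc, fallback))
        return pd.DataFrame(
            rows, columns=["cluster", "gene_id", "centroid_corr", "max_abs_log2FC", "fallback"]
        )


def kmeans_cluster(traj: TrajectoryMatrix, k: int, seed: int = 0, n_restarts: int = 25) -> ClusterResults:
    """Functional wrapper: fit :class:`TrajectoryKMeans` and return results."""
    return TrajectoryKMeans(traj, k=k, seed=seed, n_restarts=n_restarts).fit()


# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------

@dataclass
class GapCurve:
    """Gap-statistic curve over candidate k.

    gap(k) = E*[log W_k] - log W_k against B uniform reference draws;
    s_k = sd_B(log W*_k) * sqrt(1 + 1/B). ``selected_k`` is the smallest
    k with gap(k) >= gap(k+1) - s_{k+1} (the last candidate if none
    qualifies).
    """

    k_values: list
    log_w: np.ndarray
    elog_w_ref: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    B: int
    selected_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "log_W": self.log_w,
                "Elog_W_ref": self.elog_w_ref,
                "gap": self.gap,
                "s_k": self.s_k,
            }
        ).set_index("k")


def _inertia(x: np.ndarray, k: int, seed: int, n_restarts: int) -> float:
    if k == 1:
        return float(((x - x.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed).fit(x)
    return float(km.inertia_)


def gap_statistic(
    traj,
    k_range=range(1, 16),
    B: int = 50,
    seed: int = 0,
    n_restarts: int = 10,
    ref_restarts: int = 4,
) -> GapCurve:
    """Gap statistic with a uniform-over-feature-ranges reference.

    Parameters
    ----------
    traj : TrajectoryMatrix or ndarray (observations × features)
    k_range : iterable of candidate k (each in [1, n))
    B : number of reference datasets (>= 10)
    seed : seed for reference draws and k-means restarts
    n_restarts, ref_restarts : k-means restarts for the data / references
    """
    x = traj.z if hasattr(traj, "z") else np.asarray(traj, float)
    if B < 10:
        raise ValueError("B must be >= 10")
    ks = sorted(int(k) for k in k_range)
    n = x.shape[0]
    if ks[0] < 1 or ks[-1] >= n:
        raise ValueError(f"k_range must lie within [1, {n})")
    lo, hi = x.min(axis=0), x.max(axis=0)
    if np.all(hi - lo == 0):
        raise ValueError("degenerate data: all points identical")
    log_w = np.array([np.log(_inertia(x, k, seed, n_restarts)) for k in ks])
    rng = np.random.default_rng(seed)
    log_w_ref = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=x.shape)
        for j, k in enumerate(ks):
            log_w_ref[b, j] = np.log(_inertia(ref, k, seed + 1 + b, ref_restarts))
    elog = log_w_ref.mean(axis=0)
    gap = elog - log_w
    s_k = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    selected = ks[-1]
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - s_k[j + 1]:
            selected = ks[j]
            break
    return GapCurve(
        k_values=ks,
        log_w=log_w,
        elog_w_ref=elog,
        gap=gap,
        s_k=s_k,
        B=B,
        selected_k=selected,
    )
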