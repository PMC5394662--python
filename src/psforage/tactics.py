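"""Producer/scrounger tactic assignment by longitudinal clustering.

Each bird's behaviour is summarized as its *cumulative scrounge
proportion* — scrounges over rewarded visits — evaluated at the end of
consecutive 2-hour active-time bins counted from its own first rewarded
event. Trajectories are aligned to a common length by truncation and
clustered with k-means (k = 2 for the headline producer/scrounger split);
the lower-mean cluster is labelled ``producer``, the higher ``scrounger``.
A separate audit (:func:`bimodality_check`) asks whether two clusters are
actually supported, by the Calinski-Harabasz index over k with a
silhouette test against a unimodal null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from ._calendar import active_seconds_elapsed
from .events import SCROUNGE, SOLVE

__all__ = [
    "TrajectorySet",
    "TacticAssignment",
    "build_trajectories",
    "longitudinal_kmeans",
    "bimodality_check",
    "running_mean_trajectory",
    "proportion_scroungers",
]


@dataclass
class TrajectorySet:
    """Aligned per-bird trajectories of cumulative scrounge proportion.

    ``values`` is a birds x bins array; ``values[b, t]`` is the bird's
    scrounges / rewarded-visits ratio over its first ``t + 1`` bins of
    active time. The final column equals the bird's overall scrounge
    proportion over the aligned window.
    """

    values: np.ndarray
    birds: list[str]
    bin_hours: float

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.birds, name="bird_id"),
            columns=[f"bin_{t + 1}" for t in range(self.n_bins)],
        )


@dataclass
class TacticAssignment:
    """Cluster labels plus summaries from longitudinal k-means.

    ``cluster_means`` (ascending) are the mean final-bin scrounge
    proportions per cluster; for k = 2, labels are ``producer`` (lower
    mean) and ``scrounger`` (higher mean).
    """

    labels: pd.Series
    cluster_means: np.ndarray
    cluster_sds: np.ndarray
    k: int
    inertia: float
    profiles: pd.DataFrame  # per-cluster mean trajectory, one row per cluster


def build_trajectories(
    events: pd.DataFrame,
    bin_hours: float = 2.0,
    min_visits: int = 50,
    weekdays_only: bool = True,
    align: str = "truncate",
) -> TrajectorySet:
    """Build aligned cumulative scrounge-proportion trajectories.

    Only rewarded events (solves and scrounges) count. Bins are measured
    in *active* experiment time (nights and weekends do not accrue),
    starting at each bird's first rewarded event. Birds with fewer than
    ``min_visits`` rewarded events are excluded. The clustering step needs
    equal-length trajectories: ``align='truncate'`` (default) cuts every
    bird to the shortest included bird's bin count; ``align='pad'``
    extends every bird to the longest count by carrying the last
    cumulative value forward.
    """
    if align not in ("truncate", "pad"):
        raise ValueError("align must be 'truncate' or 'pad'")
    rewarded = events[events["kind"].isin([SOLVE, SCROUNGE])].copy()
    if rewarded.empty:
        raise ValueError("no rewarded events")
    counts = rewarded.groupby("bird_id").size()
    keep = counts[counts >= min_visits].index
    rewarded = rewarded[rewarded["bird_id"].isin(keep)]
    if rewarded.empty:
        raise ValueError(f"no bird reaches the {min_visits}-visit threshold")

    act = active_seconds_elapsed(
        rewarded["time"].to_numpy(float), weekdays_only=weekdays_only
    )
    rewarded["active_s"] = act
    t_end = act.max()
    bin_s = bin_hours * 3600.0

    birds = []
    n_avail = {}
    for b, grp in rewarded.groupby("bird_id", sort=True):
        start = grp["active_s"].min()
        n_avail[b] = int(np.floor((t_end - start) / bin_s)) + 1
        birds.append(b)

    L = min(n_avail.values()) if align == "truncate" else max(n_avail.values())
    values = np.zeros((len(birds), L))
    for i, b in enumerate(birds):
        grp = rewarded[rewarded["bird_id"] == b].sort_values("active_s", kind="stable")
        a = grp["active_s"].to_numpy(float)
        is_scr = (grp["kind"] == SCROUNGE).to_numpy()
        rel_bin = np.floor((a - a[0]) / bin_s).astype(int)
        cum_scr = np.cumsum(is_scr)
        cum_all = np.arange(1, len(a) + 1)
        for t in range(L):
            idx = np.searchsorted(rel_bin, t, side="right") - 1
            # bins with no events carry the previous cumulative ratio
            values[i, t] = cum_scr[idx] / cum_all[idx] if idx >= 0 else 0.0
    return TrajectorySet(values=values, birds=birds, bin_hours=bin_hours)


def longitudinal_kmeans(
    traj: TrajectorySet,
    k: int = 2,
    n_starts: int = 10,
    seed: int = 1,
) -> TacticAssignment:
    """Cluster trajectories as L-dimensional points with k-means.

    Euclidean distance, best of ``n_starts`` restarts by within-cluster
    sum of squares, deterministic given ``seed``. Clusters are reported in
    ascending order of mean final-bin proportion; for k = 2 labels are
    ``producer`` / ``scrounger``, otherwise ``cluster_1..k``.
    """
    X = np.asarray(traj.values, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} birds, got {X.shape[0]}")
    if k >= 2 and np.allclose(X, X[0]):
        raise ValueError("degenerate clustering: all trajectories identical")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    raw = km.fit_predict(X)

    final = X[:, -1]
    means = np.array([final[raw == c].mean() for c in range(k)])
    order = np.argsort(means, kind="stable")  # ties break toward lower index
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    if k == 2:
        names = ["producer", "scrounger"]
    else:
        names = [f"cluster_{r + 1}" for r in range(k)]
    labels = pd.Series(
        [names[rank[c]] for c in raw],
        index=pd.Index(traj.birds, name="bird_id"),
        name="tactic",
    )
    sds = np.array([final[raw == c].std(ddof=0) for c in range(k)])
    profiles = pd.DataFrame(
        [X[raw == c].mean(axis=0) for c in order],
        index=[names[r] for r in range(k)],
        columns=[f"bin_{t + 1}" for t in range(X.shape[1])],
    )
    return TacticAssignment(
        labels=labels,
        cluster_means=means[order],
        cluster_sds=sds[order],
        k=k,
        inertia=float(km.inertia_),
        profiles=profiles,
    )


@dataclass
class BimodalityResult:
    selected_k: int
    ch_scores: dict[int, float]
    silhouette_k2: float
    silhouette_null_q95: float


def bimodality_check(
    traj: TrajectorySet,
    k_max: int = 4,
    n_null: int = 100,
    seed: int = 1,
) -> BimodalityResult:
    """Audit how many clusters the trajectory set supports.

    Candidate k = 2..k_max are compared by the Calinski-Harabasz index
    (undefined at k = 1). Because CH cannot speak for unimodality, the
    k = 2 silhouette is additionally compared with its distribution under
    a matched unimodal Gaussian null (same per-bin mean and covariance
    diagonal); when the observed silhouette does not exceed the null's
    95th percentile, k = 1 is reported.
    """
    X = np.asarray(traj.values, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 birds")
    k_max = min(k_max, X.shape[0] - 1)
    ch = {}
    labelings = {}
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < k:
            continue
        ch[k] = float(calinski_harabasz_score(X, lab))
        labelings[k] = lab
    if not ch:
        return BimodalityResult(1, {}, np.nan, np.nan)
    k_best = max(ch, key=lambda k: ch[k])

    sil_obs = float(silhouette_score(X, labelings[2])) if 2 in labelings else np.nan
    rng = np.random.default_rng(seed)
    # unimodal Gaussian null with the *empirical covariance* (trajectory
    # bins are strongly correlated; an independent-bin null would be far
    # too easy to beat)
    mu = X.mean(axis=0)
    Xc = X - mu
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    scale = sv / np.sqrt(max(X.shape[0] - 1, 1))
    null = np.empty(n_null)
    for i in range(n_null):
        Z = rng.normal(size=(X.shape[0], len(sv))) * scale
        sample = mu + Z @ Vt
        lab = KMeans(n_clusters=2, n_init=3, random_state=seed).fit_predict(sample)
        null[i] = silhouette_score(sample, lab)
    q95 = float(np.quantile(null, 0.95))
    if not np.isnan(sil_obs) and sil_obs <= q95:
        k_best = 1
    return BimodalityResult(k_best, ch, sil_obs, q95)


def running_mean_trajectory(
    events: pd.DataFrame, window_visits: int = 20
) -> dict[str, np.ndarray]:
    """Sliding-window scrounge proportion over each bird's rewarded visits.

    For plotting individual trajectories: entry ``v`` of a bird's series
    is the proportion of its rewarded visits ``v+1 .. v+window`` that were
    scrounges, so the series starts at visit ``window_visits``. Birds with
    fewer rewarded visits than the window are omitted.
    """
    out: dict[str, np.ndarray] = {}
    rewarded = events[events["kind"].isin([SOLVE, SCROUNGE])]
    for b, grp in rewarded.groupby("bird_id", sort=True):
        is_scr = (
            grp.sort_values("time", kind="stable")["kind"] == SCROUNGE
        ).to_numpy(float)
        if len(is_scr) < window_visits:
            continue
        c = np.concatenate([[0.0], np.cumsum(is_scr)])
        out[b] = (c[window_visits:] - c[:-window_visits]) / window_visits
    return out


def proportion_scroungers(
    labels: pd.Series, replicate: pd.Series | None = None
) -> pd.Series | float:
    """Fraction of clustered birds labelled ``scrounger``.

    With ``replicate`` (a bird -> replicate mapping), returns one
    proportion per replicate; otherwise a single float.
    """
    is_scr = labels == "scrounger"
    if replicate is None:
        return float(is_scr.mean())
    rep = replicate.reindex(labels.index)
    return is_scr.groupby(rep).mean().rename("proportion_scroungers")
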