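"""Association networks and stratified data-stream permutations.

Associations follow the gambit of the group: two birds are associated in
every gathering event they share, and the edge weight is the simple ratio
index (SRI),

    SRI(i, j) = x / (x + y),

where ``x`` is the number of events containing both and ``y`` the number
containing exactly one of them — equivalently the Jaccard index of their
event sets. Weights run from 0 (never in the same group) to 1 (always in
the same group).

The permutation null swaps individuals between gathering events within
date x location strata ("checkerboard" 2x2 swaps), preserving every
event's size and every bird's sighting count inside each stratum. Chains
of such swaps generate the data-stream permutation distribution used for
network regression significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .gatherings import GatheringEvent, GroupByIndividual

__all__ = [
    "association_matrix",
    "node_metrics",
    "average_group_size_per_bird",
    "gbi_metric",
    "PermutedStream",
    "permute_stream",
    "attempt_swap",
]


def association_matrix(gbi: GroupByIndividual) -> pd.DataFrame:
    """Simple-ratio association matrix from a group-by-individual matrix.

    Returns an N x N symmetric DataFrame (bird x bird) with zero diagonal
    and entries in [0, 1]. Birds attending zero events get all-zero rows.
    """
    X = gbi.matrix.astype(float)
    if X.shape[0] < 1:
        raise ValueError("need at least one gathering event")
    both = X.T @ X  # events containing both i and j
    attended = np.diag(both).copy()
    either = attended[:, None] + attended[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(either > 0, both / np.where(either > 0, either, 1.0), 0.0)
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=gbi.birds, columns=gbi.birds)


def average_group_size_per_bird(
    events: list[GatheringEvent] | GroupByIndividual,
) -> pd.Series:
    """Mean size of the gathering events each bird attended (self included).

    Accepts either the detected event list or a GBI (where event size is
    the row sum). Birds attending no events are absent from the output.
    """
    if isinstance(events, GroupByIndividual):
        sizes = events.matrix.sum(axis=1).astype(float)
        att = events.matrix.astype(float)
        n_att = att.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(n_att > 0, (att.T @ sizes) / np.where(n_att > 0, n_att, 1), np.nan)
        s = pd.Series(mean, index=events.birds, name="avg_group_size")
        return s[n_att > 0]
    per_bird: dict[str, list[int]] = {}
    for e in events:
        for b in e.members:
            per_bird.setdefault(b, []).append(e.size)
    return pd.Series(
        {b: float(np.mean(v)) for b, v in sorted(per_bird.items())},
        name="avg_group_size",
        dtype=float,
    )


def node_metrics(
    A: pd.DataFrame,
    events: list[GatheringEvent] | GroupByIndividual | None = None,
) -> pd.DataFrame:
    """Per-bird network metrics from an association matrix.

    * ``strength`` — weighted degree, the row sum of associations (total
      interaction rate; overall sociability);
    * ``degree`` — count of nonzero associations (gregariousness);
    * ``betweenness`` — number of shortest paths between all node pairs
      passing through the focal bird, computed on the binarized graph
      (edge iff association > 0), unnormalized, with tied shortest paths
      splitting the pair's count evenly;
    * ``avg_group_size`` — mean attended-event size, when ``events`` is
      given.

    Isolates get betweenness 0.
    """
    birds = list(A.index)
    W = A.to_numpy(float)
    strength = W.sum(axis=1)
    degree = (W > 0).sum(axis=1)

    G = nx.from_numpy_array((W > 0).astype(int))
    btw = nx.betweenness_centrality(G, normalized=False)
    out = pd.DataFrame(
        {
            "strength": strength,
            "degree": degree,
            "betweenness": [btw[i] for i in range(len(birds))],
        },
        index=pd.Index(birds, name="bird_id"),
    )
    if events is not None:
        out["avg_group_size"] = average_group_size_per_bird(events)
    return out


def gbi_metric(gbi: GroupByIndividual, metric: str) -> pd.Series:
    """Compute one sociability metric directly from a GBI.

    ``metric`` is one of ``strength``, ``degree``, ``betweenness``,
    ``avg_group_size``. Used inside permutation chains where the GBI is
    the object being shuffled.
    """
    if metric == "avg_group_size":
        sizes = gbi.matrix.sum(axis=1).astype(float)
        att = gbi.matrix.astype(float)
        n_att = att.sum(axis=0)
        vals = np.where(n_att > 0, (att.T @ sizes) / np.where(n_att > 0, n_att, 1), 0.0)
        return pd.Series(vals, index=gbi.birds, name=metric)
    A = association_matrix(gbi)
    if metric == "strength":
        return A.sum(axis=1).rename(metric)
    if metric == "degree":
        return (A > 0).sum(axis=1).rename(metric)
    if metric == "betweenness":
        G = nx.from_numpy_array((A.to_numpy() > 0).astype(int))
        btw = nx.betweenness_centrality(G, normalized=False)
        return pd.Series(
            [btw[i] for i in range(len(gbi.birds))], index=gbi.birds, name=metric
        )
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class PermutedStream:
    """A GBI after a chain of stratified checkerboard swaps."""

    gbi: GroupByIndividual
    n_attempts: int = 0
    n_swaps: int = 0
    swap_log: list[tuple[int, int, int, int, str]] = field(default_factory=list)


def _stratum_rows(gbi: GroupByIndividual) -> dict[str, np.ndarray]:
    rows: dict[str, list[int]] = {}
    for k, s in enumerate(gbi.strata):
        rows.setdefault(str(s), []).append(k)
    return {s: np.asarray(v) for s, v in rows.items()}


def attempt_swap(
    mat: np.ndarray,
    stratum_rows: dict[str, np.ndarray],
    stratum_names: list[str],
    stratum_weights: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, int, int, int, str] | None:
    """One checkerboard-swap attempt; mutates ``mat`` in place on success.

    Picks a stratum (weighted by its number of event pairs), two distinct
    events in it and two distinct birds; if the 2x2 submatrix is
    (1,0;0,1) or (0,1;1,0) it is flipped to the opposite pattern, which
    leaves all stratum-wise row and column sums unchanged. Returns the
    swap (row1, row2, col1, col2, stratum) or None if the draw was not
    swappable.
    """
    s_idx = rng.choice(len(stratum_names), p=stratum_weights)
    rows = stratum_rows[stratum_names[s_idx]]
    if rows.size < 2:
        return None
    r1, r2 = rows[rng.choice(rows.size, size=2, replace=False)]
    n_birds = mat.shape[1]
    c1, c2 = rng.choice(n_birds, size=2, replace=False)
    a, b = mat[r1, c1], mat[r1, c2]
    c, d = mat[r2, c1], mat[r2, c2]
    if a + d == 2 and b + c == 0 or a + d == 0 and b + c == 2:
        mat[r1, c1], mat[r1, c2] = b, a
        mat[r2, c1], mat[r2, c2] = d, c
        return (int(r1), int(r2), int(c1), int(c2), stratum_names[s_idx])
    return None


def make_swapper(gbi: GroupByIndividual):
    """Precompute stratum bookkeeping; returns (mat_copy, attempt_fn).

    ``attempt_fn(rng)`` performs one swap attempt on the shared matrix and
    returns the swap tuple or None. Strata with fewer than two events can
    never swap and are excluded from the draw.
    """
    mat = gbi.matrix.copy()
    srows = _stratum_rows(gbi)
    names = [s for s in srows if srows[s].size >= 2]
    if not names:
        def noop(rng):
            return None
        return mat, noop
    pairs = np.array([srows[s].size * (srows[s].size - 1) / 2 for s in names])
    weights = pairs / pairs.sum()

    def attempt(rng):
        return attempt_swap(mat, srows, names, weights, rng)

    return mat, attempt


def permute_stream(
    gbi: GroupByIndividual,
    n_swaps: int,
    rng: np.random.Generator,
    log_swaps: bool = False,
) -> PermutedStream:
    """Run ``n_swaps`` checkerboard-swap attempts on a copy of the GBI.

    Swaps accumulate serially (the data-stream permutation chain). Strata
    without any swappable 2x2 submatrix are simply never changed; a
    single-event stratum leaves the matrix untouched by construction.
    """
    mat, attempt = make_swapper(gbi)
    out = PermutedStream(
        gbi=GroupByIndividual(mat, list(gbi.birds), gbi.strata.copy(),
                              list(gbi.event_ids))
    )
    # the GroupByIndividual constructor copies dtype-compatible arrays by
    # reference; make sure the swapper's matrix is the one carried along
    out.gbi.matrix = mat
    for _ in range(int(n_swaps)):
        swap = attempt(rng)
        out.n_attempts += 1
        if swap is not None:
            out.n_swaps += 1
            if log_swaps:
                out.swap_log.append(swap)
    return out
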