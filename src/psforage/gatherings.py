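"""Gathering-event detection in feeder visit streams.

Flocking birds arrive at feeders in temporally clustered bursts. Within
each feeder-day, detection times (visit-interval midpoints) are modelled
as a 1-D Gaussian mixture; the number of components is selected by BIC and
each detection is assigned to its maximum-responsibility component. Each
component becomes one *gathering event* whose members are the distinct
birds assigned to it — the "gambit of the group" then treats all members
of an event as associated.

Mixtures are fitted on the time axis only, one feeder-day at a time, so
the date x location strata used by the permutation null are preserved by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._calendar import day_index

__all__ = ["GatheringEvent", "GroupByIndividual", "detect_gatherings", "build_gbi"]


@dataclass(frozen=True)
class GatheringEvent:
    """One detected flocking burst at a feeder."""

    event_id: str
    feeder_id: str
    date: int
    start_s: float
    end_s: float
    members: tuple[str, ...]
    n_detections: int

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def stratum(self) -> str:
        return f"{self.date}|{self.feeder_id}"


@dataclass
class GroupByIndividual:
    """Binary events x individuals matrix with per-row strata.

    ``matrix[k, j] = 1`` iff bird ``birds[j]`` attended event ``k``;
    ``strata[k]`` is the "date|feeder" label of event ``k``. Column order
    follows ``birds`` (sorted roster order) and is fixed across the
    analysis.
    """

    matrix: np.ndarray
    birds: list[str]
    strata: np.ndarray
    event_ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("GBI matrix must be 2-D")
        if self.matrix.shape[0] != len(self.strata):
            raise ValueError("one stratum label required per event row")
        if ((self.matrix != 0) & (self.matrix != 1)).any():
            raise ValueError("GBI entries must be binary")

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_birds(self) -> int:
        return self.matrix.shape[1]

    def copy(self) -> "GroupByIndividual":
        return GroupByIndividual(
            self.matrix.copy(), list(self.birds), self.strata.copy(),
            list(self.event_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.birds)
        df.insert(0, "stratum", self.strata)
        df.insert(0, "event_id", self.event_ids)
        return df


#: extra components must improve BIC by at least this much ("positive
#: evidence" on the Kass-Raftery scale); suppresses spurious splits whose
#: BIC ties within noise, while genuine event splits win by hundreds
BIC_PARSIMONY_MARGIN = 6.0


def _fit_mixture_1d(
    times: np.ndarray, max_components: int, seed: int,
    margin: float = BIC_PARSIMONY_MARGIN,
) -> np.ndarray:
    """Assign each time to a BIC-selected Gaussian mixture component.

    Component count is the smallest k whose BIC lies within ``margin`` of
    the minimum over 1..max_components.
    """
    X = times.reshape(-1, 1)
    n = len(times)
    k_max = int(min(max_components, n))
    fits, bics = [], []
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=1.0,  # 1 s^2 floor avoids singular components
            n_init=5,
            init_params="kmeans",
            random_state=seed,
        )
        gm.fit(X)
        fits.append(gm)
        bics.append(gm.bic(X))
    bics = np.asarray(bics)
    best = int(np.flatnonzero(bics <= bics.min() + margin)[0])
    return fits[best].predict(X)


def detect_gatherings(
    feeder_visits: pd.DataFrame,
    max_components: int | None = None,
    min_event_size: int = 1,
    trivial_single: bool = True,
    seed: int = 0,
) -> list[GatheringEvent]:
    """Detect gathering events in a feeder visit stream.

    Parameters
    ----------
    feeder_visits
        Visit records (any number of feeders/days) with columns
        ``device_id, bird_id, arrive_s, depart_s``. Each feeder-day is
        modelled independently. The detection time of a visit is its
        interval midpoint.
    max_components
        Upper bound on mixture components per feeder-day; defaults to
        ``ceil(n_detections / 5)`` capped at 25.
    min_event_size
        Discard events with fewer distinct members than this.
    trivial_single
        With fewer than two detections in a feeder-day, emit one trivial
        event (default) rather than nothing.
    seed
        Sub-seed for the k-means initialization (5 restarts per fit);
        identical data and seed give identical events.

    Returns
    -------
    list of :class:`GatheringEvent`, ordered by (date, feeder, start).
    Every detection is assigned to exactly one event (a partition of the
    feeder-day), save for events dropped by ``min_event_size``.
    """
    if feeder_visits.empty:
        return []
    visits = feeder_visits.copy()
    if "device_type" in visits:
        visits = visits[visits["device_type"] == "feeder"]
    visits["midpoint"] = 0.5 * (
        visits["arrive_s"].to_numpy(float) + visits["depart_s"].to_numpy(float)
    )
    visits["date"] = day_index(visits["midpoint"].to_numpy())

    events: list[GatheringEvent] = []
    for (date, feeder), grp in visits.groupby(["date", "device_id"], sort=True):
        times = grp["midpoint"].to_numpy(float)
        birds = grp["bird_id"].to_numpy(object)
        n = len(grp)
        if n < 2:
            if trivial_single and n == 1:
                labels = np.zeros(1, dtype=int)
            else:
                continue
        else:
            k_cap = max_components
            if k_cap is None:
                k_cap = min(int(np.ceil(n / 5)), 25)
            labels = _fit_mixture_1d(times, k_cap, seed)

        for ci, comp in enumerate(np.unique(labels)):
            mask = labels == comp
            members = tuple(sorted(set(birds[mask])))
            if len(members) < min_event_size:
                continue
            events.append(
                GatheringEvent(
                    event_id=f"{feeder}_d{date}_e{ci}",
                    feeder_id=str(feeder),
                    date=int(date),
                    start_s=float(times[mask].min()),
                    end_s=float(times[mask].max()),
                    members=members,
                    n_detections=int(mask.sum()),
                )
            )
    events.sort(key=lambda e: (e.date, e.feeder_id, e.start_s))
    return events


def build_gbi(
    events: list[GatheringEvent], birds: list[str] | None = None
) -> GroupByIndividual:
    """Build the binary group-by-individual matrix from gathering events.

    ``birds`` is the authoritative roster defining column order (sorted
    when not given). A bird appearing several times in one event
    contributes a single 1. Raises if an event member is missing from the
    roster.
    """
    if not events:
        raise ValueError("no gathering events to build a GBI from")
    seen = sorted({b for e in events for b in e.members})
    if birds is None:
        birds = seen
    else:
        birds = list(birds)
        missing = set(seen) - set(birds)
        if missing:
            raise ValueError(
                f"birds present in events but absent from roster: {sorted(missing)}"
            )
    col = {b: j for j, b in enumerate(birds)}
    mat = np.zeros((len(events), len(birds)), dtype=np.int8)
    for k, e in enumerate(events):
        for b in e.members:
            mat[k, col[b]] = 1
    strata = np.array([e.stratum for e in events])
    return GroupByIndividual(
        matrix=mat,
        birds=birds,
        strata=strata,
        event_ids=[e.event_id for e in events],
    )
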