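"""Puzzle-box visit classification.

A puzzle-box door opens when a bird performs the solving action and closes
one second after the bird leaves the perch. Any *different* bird that lands
within that second feeds from the open box without solving — a scrounge —
and resets the one-second countdown, up to a hardware cap of three
scrounges per solve, after which the door shuts. This module replays that
door logic deterministically over a sorted RFID visit stream and labels
every visit as one of:

* ``SOLVE``      — bird opened the closed door (chain position 0);
* ``SCROUNGE``   — different bird landed within the window while the door
  was open (chain positions 1-3);
* ``REVISIT``    — a bird already rewarded in the open chain returned
  within the window (not rewarded);
* ``CONTACT``    — visit to a closed door.

It also derives the per-bird exposure summaries used downstream: time of
first contact (in active-time seconds), latency to learn (cumulative
closed-door seconds before the first solve) and rewarded-visit counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._calendar import ACTIVE_END_S, ACTIVE_START_S, active_seconds_elapsed

logger = logging.getLogger(__name__)

SOLVE = "SOLVE"
SCROUNGE = "SCROUNGE"
CONTACT = "CONTACT"
REVISIT = "REVISIT"

EVENT_COLUMNS = [
    "bird_id",
    "time",
    "depart_s",
    "kind",
    "chain_id",
    "chain_position",
    "device_id",
    "subpop",
    "replicate",
]

__all__ = [
    "SolveChain",
    "classify_visits",
    "classify_all",
    "run_door_automaton",
    "first_contact_time",
    "latency_to_learn",
    "rewarded_counts",
    "exposure_summaries",
    "SOLVE",
    "SCROUNGE",
    "CONTACT",
    "REVISIT",
]


@dataclass
class SolveChain:
    """One solve plus its within-window scrounges (at most three)."""

    chain_id: str
    solver: str
    scroungers: list[str] = field(default_factory=list)
    door_close_time: float = np.nan

    @property
    def size(self) -> int:
        return 1 + len(self.scroungers)


def _validate_records(records: pd.DataFrame) -> None:
    arrive = records["arrive_s"].to_numpy(float)
    depart = records["depart_s"].to_numpy(float)
    if np.any(depart < arrive):
        bad = int(np.argmax(depart < arrive))
        raise ValueError(f"depart_s < arrive_s at input row {bad}")
    if np.any(np.diff(arrive) < 0):
        raise ValueError("records must be sorted by arrive_s")
    # overlapping intervals of the same bird are physically impossible
    for bird, grp in records.groupby("bird_id", sort=False):
        a = grp["arrive_s"].to_numpy(float)
        d = grp["depart_s"].to_numpy(float)
        if np.any(a[1:] < d[:-1]):
            raise ValueError(f"overlapping visit intervals for bird {bird!r}")


def classify_visits(
    records: pd.DataFrame,
    window_s: float = 1.0,
    max_scrounges: int = 3,
    chain_prefix: str = "c",
    validate: bool = True,
) -> tuple[pd.DataFrame, list[SolveChain]]:
    """Classify the visit stream of a single puzzle-box.

    Parameters
    ----------
    records
        Visit records of one device, sorted by ``arrive_s``. Required
        columns: ``bird_id, arrive_s, depart_s, opened``; ``device_id``,
        ``subpop`` and ``replicate`` are carried through when present.
    window_s
        Door-open window after a rewarded bird departs (1.0 s by default,
        inclusive on the 1/16-s grid: a tie at exactly ``window_s`` counts
        as within-window).
    max_scrounges
        Hardware cap on scrounges per solve; the door shuts upon detection
        of the cap-th scrounger.

    Returns
    -------
    events, chains
        ``events`` has one row per input record (same order) with columns
        ``bird_id, time, depart_s, kind, chain_id, chain_position, ...``;
        ``chains`` lists every :class:`SolveChain` in time order.
    """
    if validate:
        _validate_records(records)

    bird = records["bird_id"].to_numpy(object)
    arrive = records["arrive_s"].to_numpy(float)
    depart = records["depart_s"].to_numpy(float)
    opened = (
        records["opened"].to_numpy(float) if "opened" in records
        else np.zeros(len(records))
    )
    kind, chain_id, chain_pos, chains = run_door_automaton(
        bird, arrive, depart, opened,
        window_s=window_s, max_scrounges=max_scrounges,
        chain_prefix=chain_prefix,
    )

    events = pd.DataFrame(
        {
            "bird_id": bird,
            "time": arrive,
            "depart_s": depart,
            "kind": kind,
            "chain_id": chain_id,
            "chain_position": chain_pos,
        },
        index=records.index,
    )
    for col in ("device_id", "subpop", "replicate"):
        if col in records:
            events[col] = records[col].to_numpy()
    return events, chains


def run_door_automaton(
    bird: np.ndarray,
    arrive: np.ndarray,
    depart: np.ndarray,
    opened: np.ndarray,
    window_s: float = 1.0,
    max_scrounges: int = 3,
    chain_prefix: str = "c",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[SolveChain]]:
    """Door-state automaton on plain arrays (the core of
    :func:`classify_visits`, without validation or table assembly)."""
    n = len(bird)
    opened = np.nan_to_num(np.asarray(opened, float), nan=0.0)

    kind = np.empty(n, dtype=object)
    chain_id = np.empty(n, dtype=object)
    chain_id[:] = None
    chain_pos = np.full(n, np.nan)

    chains: list[SolveChain] = []
    cur: SolveChain | None = None
    cur_members: set = set()
    last_rewarded_depart = -np.inf
    n_chains = 0

    for i in range(n):
        t = arrive[i]
        if cur is not None and t > last_rewarded_depart + window_s:
            # window expired unconsumed -> door closed
            cur.door_close_time = last_rewarded_depart + window_s
            cur = None
        if cur is None:
            if opened[i] == 1:
                n_chains += 1
                cid = f"{chain_prefix}{n_chains}"
                cur = SolveChain(chain_id=cid, solver=bird[i])
                cur_members = {bird[i]}
                chains.append(cur)
                last_rewarded_depart = depart[i]
                kind[i], chain_id[i], chain_pos[i] = SOLVE, cid, 0
            else:
                kind[i] = CONTACT
        else:
            if bird[i] in cur_members:
                kind[i], chain_id[i] = REVISIT, cur.chain_id
            else:
                if opened[i] == 1:
                    logger.warning(
                        "record %d flagged opened=1 while door already open; "
                        "treated as SCROUNGE",
                        i,
                    )
                cur.scroungers.append(bird[i])
                cur_members.add(bird[i])
                last_rewarded_depart = depart[i]
                pos = len(cur.scroungers)
                kind[i], chain_id[i], chain_pos[i] = SCROUNGE, cur.chain_id, pos
                if pos >= max_scrounges:
                    # door begins to shut on detection of the cap-th scrounger
                    cur.door_close_time = depart[i]
                    cur = None
    if cur is not None:
        cur.door_close_time = last_rewarded_depart + window_s
    return kind, chain_id, chain_pos, chains


def classify_all(
    records: pd.DataFrame, window_s: float = 1.0, max_scrounges: int = 3
) -> tuple[pd.DataFrame, list[SolveChain]]:
    """Classify a multi-device stream, one door automaton per puzzle-box.

    Feeder records (``device_type != 'puzzlebox'``) are ignored. Chain ids
    are prefixed with the device id so they stay globally unique.
    """
    if "device_type" in records:
        records = records[records["device_type"] == "puzzlebox"]
    parts, chains = [], []
    for dev, grp in records.groupby("device_id", sort=True):
        grp = grp.sort_values("arrive_s", kind="stable")
        ev, ch = classify_visits(
            grp, window_s=window_s, max_scrounges=max_scrounges,
            chain_prefix=f"{dev}_c",
        )
        parts.append(ev)
        chains.extend(ch)
    if not parts:
        return pd.DataFrame(columns=EVENT_COLUMNS), []
    events = pd.concat(parts).sort_values(["time"], kind="stable")
    return events.reset_index(drop=True), chains


def first_contact_time(
    events: pd.DataFrame,
    experiment_start: float = 0.0,
    active_start_s: float = ACTIVE_START_S,
    active_end_s: float = ACTIVE_END_S,
    weekdays_only: bool = True,
) -> pd.Series:
    """Active-time seconds from experiment start to each bird's first detection.

    Nights (outside the active window) and, by default, weekends do not
    accrue: a bird first seen at 07:00 on day 2 of a 06:00-18:00 schedule
    has a first-contact time of 12 h + 1 h = 46 800 s. Any detection kind
    counts (the first contact is typically neither a solve nor a scrounge).
    Birds never detected are absent from the output.
    """
    first = events.groupby("bird_id")["time"].min()
    elapsed = active_seconds_elapsed(
        first.to_numpy(float), active_start_s, active_end_s, weekdays_only
    ) - active_seconds_elapsed(
        experiment_start, active_start_s, active_end_s, weekdays_only
    )
    return pd.Series(elapsed, index=first.index, name="first_contact_s")


def latency_to_learn(events: pd.DataFrame) -> pd.Series:
    """Cumulative closed-door seconds before each bird's first solve.

    Sums visit durations of ``CONTACT`` events (closed door) occurring
    before the bird's first ``SOLVE``; open-door time spent scrounging is
    excluded. Birds that never solve get a missing value.
    """
    out = {}
    for b, grp in events.groupby("bird_id"):
        solves = grp.loc[grp["kind"] == SOLVE, "time"]
        if solves.empty:
            out[b] = np.nan
            continue
        t0 = solves.iloc[0]
        pre = grp[(grp["kind"] == CONTACT) & (grp["time"] < t0)]
        out[b] = float((pre["depart_s"] - pre["time"]).sum())
    return pd.Series(out, name="latency_to_learn_s", dtype=float)


def rewarded_counts(events: pd.DataFrame, min_visits: int = 50) -> pd.DataFrame:
    """Per-bird solve/scrounge tallies with the minimum-visits filter flag.

    Only rewarded events (solves and scrounges) count; revisits and
    contacts are excluded. ``passes_min_visits`` is inclusive at the
    threshold (a bird with exactly ``min_visits`` rewarded visits passes).
    """
    counts = (
        events.groupby("bird_id")["kind"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[SOLVE, SCROUNGE, CONTACT, REVISIT], fill_value=0)
    )
    out = pd.DataFrame(
        {
            "n_solves": counts[SOLVE],
            "n_scrounges": counts[SCROUNGE],
        }
    )
    out["n_rewarded"] = out["n_solves"] + out["n_scrounges"]
    out["passes_min_visits"] = out["n_rewarded"] >= min_visits
    return out


def exposure_summaries(
    events: pd.DataFrame,
    experiment_start: float = 0.0,
    min_visits: int = 50,
) -> pd.DataFrame:
    """Assemble the full per-bird exposure table.

    Columns: ``first_contact_s``, ``latency_to_learn_s`` (NaN for
    never-solvers), ``n_solves``, ``n_scrounges``, ``n_rewarded``,
    ``passes_min_visits``; indexed by bird.
    """
    out = rewarded_counts(events, min_visits=min_visits)
    out.insert(0, "first_contact_s", first_contact_time(events, experiment_start))
    out.insert(1, "latency_to_learn_s", latency_to_learn(events))
    out.index.name = "bird_id"
    return out
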