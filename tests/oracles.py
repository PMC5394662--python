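"""Independent reference implementations used only as test oracles.

Each oracle is written directly from the rule definitions, in the most
literal style possible, deliberately sharing no code with the package:
the door automaton replays the physical door timeline; the simple-ratio
index counts explicit event sets; betweenness enumerates every simple
path. They are slow and only meant for small inputs.
"""

from __future__ import annotations

import itertools

import numpy as np


def door_automaton_reference(records, window=1.0, max_scrounges=3):
    """Literal replay of the puzzle-box door rules.

    ``records``: list of (bird, arrive, depart, opened) sorted by arrive.
    Returns a list of event kinds, one per record.

    Rules: a visit with opened=1 at a closed door is a SOLVE and opens the
    door. While the door is open, a bird not yet rewarded in the current
    chain arriving no later than ``window`` after the previous rewarded
    bird's departure is a SCROUNGE; a bird already rewarded in the chain
    is a REVISIT. The door shuts on detection of the max_scrounges-th
    scrounger, or once the window elapses unconsumed. Everything else is
    a CONTACT.
    """
    kinds = []
    door_open = False
    rewarded_members = []
    window_until = -np.inf  # door stays open to arrivals <= this time

    for bird, arrive, depart, opened in records:
        if door_open and arrive > window_until:
            door_open = False
        if not door_open:
            if opened == 1:
                kinds.append("SOLVE")
                door_open = True
                rewarded_members = [bird]
                window_until = depart + window
            else:
                kinds.append("CONTACT")
        else:
            if bird in rewarded_members:
                kinds.append("REVISIT")
            else:
                kinds.append("SCROUNGE")
                rewarded_members.append(bird)
                window_until = depart + window
                if len(rewarded_members) - 1 >= max_scrounges:
                    door_open = False
    return kinds


def sri_reference(gbi_matrix):
    """Simple ratio index by explicit set counting over events."""
    K, N = gbi_matrix.shape
    event_sets = [set(np.flatnonzero(gbi_matrix[k])) for k in range(K)]
    A = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            x = sum(1 for e in event_sets if i in e and j in e)
            y = sum(1 for e in event_sets if (i in e) != (j in e))
            A[i, j] = x / (x + y) if (x + y) > 0 else 0.0
    return A


def betweenness_reference(adj):
    """Unnormalized betweenness by exhaustive simple-path enumeration.

    For every ordered pair (s, t), all simple paths are enumerated; the
    shortest length is found and each intermediate node of each shortest
    path receives 1/(number of shortest paths). Pairs are counted once
    (s < t). Exponential: N <= 9 only.
    """
    N = adj.shape[0]
    btw = np.zeros(N)

    def all_simple_paths(s, t):
        paths = []
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nxt in range(N):
                if adj[node, nxt] and nxt not in path:
                    stack.append((nxt, path + [nxt]))
        return paths

    for s in range(N):
        for t in range(s + 1, N):
            paths = all_simple_paths(s, t)
            if not paths:
                continue
            d = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == d]
            for p in shortest:
                for v in p[1:-1]:
                    btw[v] += 1.0 / len(shortest)
    return btw


def active_seconds_reference(t, active_start=6 * 3600, active_end=18 * 3600,
                             weekdays_only=True):
    """Walk the calendar second block by second block."""
    total = 0.0
    day = 0
    while True:
        day_start = day * 86400.0
        if day_start >= t:
            break
        is_active_day = (day % 7 < 5) if weekdays_only else True
        if is_active_day:
            lo = day_start + active_start
            hi = min(day_start + active_end, t)
            if hi > lo:
                total += hi - lo
        day += 1
    return total


def enumerate_gbi_matrices(K, N, require_nonempty_rows=False):
    """Yield every binary K x N matrix (2^(K*N) of them)."""
    for bits in itertools.product([0, 1], repeat=K * N):
        mat = np.array(bits, dtype=np.int8).reshape(K, N)
        if require_nonempty_rows and (mat.sum(axis=1) == 0).any():
            continue
        yield mat


def reachable_checkerboard_states(mat, strata):
    """All GBI states reachable by stratified checkerboard swaps (BFS)."""
    strata = np.asarray(strata)
    start = mat.astype(np.int8)
    seen = {start.tobytes()}
    frontier = [start]
    K, N = start.shape
    by_stratum = {}
    for k in range(K):
        by_stratum.setdefault(str(strata[k]), []).append(k)
    while frontier:
        cur = frontier.pop()
        for rows in by_stratum.values():
            for r1, r2 in itertools.combinations(rows, 2):
                for c1, c2 in itertools.combinations(range(N), 2):
                    sub = (cur[r1, c1], cur[r1, c2], cur[r2, c1], cur[r2, c2])
                    if sub in ((1, 0, 0, 1), (0, 1, 1, 0)):
                        nxt = cur.copy()
                        nxt[r1, c1], nxt[r1, c2] = cur[r1, c2], cur[r1, c1]
                        nxt[r2, c1], nxt[r2, c2] = cur[r2, c2], cur[r2, c1]
                        b = nxt.tobytes()
                        if b not in seen:
                            seen.add(b)
                            frontier.append(nxt)
    return seen
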