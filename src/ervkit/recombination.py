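"""Two-parent recombination detection by minimal-mismatch segmentation.

Both candidate parents are globally aligned to the query; each query
position then costs 0 if it matches the active parent's aligned base
and 1 otherwise (a parent gap counts as a mismatch).  A two-state
dynamic program over query positions, with a switch penalty sigma,
yields the minimal-cost per-position parent labeling:

    cost(labels) = mismatches-to-active-parent + sigma * switches.

Breakpoints falling in runs where either label is equally optimal are
reported at the run midpoint, with the ambiguous interval retained.
An exhaustive oracle over all labelings with at most two switches
verifies the DP on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import global_align


@dataclass
class Segmentation:
    """Per-position parental assignment of a query between two parents."""

    labels: str                                  # 'A'/'B' per query position
    segments: list[tuple[str, int, int]]         # (parent, start0, end0)
    breakpoints: list[int]                       # position of first base of
                                                 # each new segment
    breakpoint_intervals: list[tuple[int, int]]  # ambiguity interval per bp
    total_cost: float
    n_switches: int

    def __post_init__(self) -> None:
        assert sum(e - s for _, s, e in self.segments) == len(self.labels)


def _per_position_costs(query: str, parent: str, **aln) -> np.ndarray:
    """cost[i] = 0 iff query position i matches its aligned parent base.

    The parent-to-query alignment uses a strongly gap-averse open
    penalty so that a long foreign segment stays one contiguous indel
    instead of being fragmented to scavenge chance matches, which would
    blur the segment boundaries.
    """
    aln.setdefault("gap_open", -20)
    aln.setdefault("gap_extend", -1)
    qa, pa, _ = global_align(query, parent,
                             band=max(len(query), len(parent)), **aln)
    cost = np.ones(len(query), dtype=np.int64)
    qi = 0
    for cq, cp in zip(qa, pa):
        if cq == "-":
            continue
        if cp != "-" and cq == cp and cq != "N":
            cost[qi] = 0
        qi += 1
    return cost


def segment_two_parents(query: str, parentA: str, parentB: str,
                        sigma: float = 3.0, **aln_kwargs) -> Segmentation:
    """Optimal two-parent segmentation of a query with switch penalty sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not query or not parentA or not parentB:
        raise ValueError("query and both parents must be non-empty")
    costs = np.stack([
        _per_position_costs(query, parentA, **aln_kwargs),
        _per_position_costs(query, parentB, **aln_kwargs),
    ]).astype(float)
    n = costs.shape[1]

    # forward: f[s, i] = min cost of labeling positions 0..i ending in s
    f = np.empty((2, n))
    f[:, 0] = costs[:, 0]
    for i in range(1, n):
        stay = f[:, i - 1]
        switch = f[::-1, i - 1] + sigma
        f[:, i] = np.minimum(stay, switch) + costs[:, i]
    total = float(f[:, -1].min())

    # backward: b[s, i] = min cost of positions i..n-1 starting in s
    b = np.empty((2, n))
    b[:, n - 1] = costs[:, n - 1]
    for i in range(n - 2, -1, -1):
        stay = b[:, i + 1]
        switch = b[::-1, i + 1] + sigma
        b[:, i] = np.minimum(stay, switch) + costs[:, i]

    # canonical labels: traceback preferring to stay, ties toward A
    lab = np.empty(n, dtype=np.int8)
    lab[-1] = 0 if f[0, -1] <= f[1, -1] else 1
    for i in range(n - 1, 0, -1):
        s = lab[i]
        stay = f[s, i - 1]
        switch = f[1 - s, i - 1] + sigma
        lab[i - 1] = s if stay <= switch else 1 - s

    # positions where either label lies on some optimal path
    both_ok = np.isclose(f + b - costs, total).all(axis=0)

    # segments and midpoint breakpoints within ambiguous runs
    bounds = [i for i in range(1, n) if lab[i] != lab[i - 1]]
    breakpoints: list[int] = []
    intervals: list[tuple[int, int]] = []
    adjusted = lab.copy()
    for bp in bounds:
        lo = bp
        while lo - 1 > 0 and both_ok[lo - 1]:
            lo -= 1
        hi = bp
        while hi < n and both_ok[hi]:
            hi += 1
        mid = (lo + hi) // 2 if hi > lo else bp
        mid = min(max(mid, 1), n - 1)
        breakpoints.append(mid)
        intervals.append((lo, hi))
    # rebuild labels from midpoint breakpoints; keep only if still optimal
    if bounds and breakpoints == sorted(breakpoints):
        seq_parents = [int(lab[0])] + [int(lab[bp]) for bp in bounds]
        candidate = np.empty(n, dtype=np.int8)
        cuts = [0] + breakpoints + [n]
        for k in range(len(cuts) - 1):
            candidate[cuts[k]:cuts[k + 1]] = seq_parents[k]
        cand_cost = float(costs[candidate, np.arange(n)].sum())
        cand_sw = int(np.count_nonzero(candidate[1:] != candidate[:-1]))
        if np.isclose(cand_cost + sigma * cand_sw, total):
            adjusted = candidate
        else:
            breakpoints = bounds
    elif bounds:
        breakpoints = bounds

    labels = "".join("AB"[int(s)] for s in adjusted)
    segments: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            segments.append((labels[start], start, i))
            start = i
    n_sw = len(segments) - 1
    return Segmentation(labels=labels, segments=segments,
                        breakpoints=[s for _, s, _ in segments[1:]],
                        breakpoint_intervals=intervals,
                        total_cost=total, n_switches=n_sw)


def oracle_segment(query: str, parentA: str, parentB: str,
                   sigma: float = 3.0, max_breakpoints: int = 2,
                   **aln_kwargs) -> Segmentation:
    """Exhaustive minimal-cost segmentation with <= max_breakpoints switches.

    Refuses queries longer than 1,000 nt; intended as an independent
    check of the dynamic program on small instances.
    """
    if len(query) > 1000:
        raise ValueError("oracle_segment is limited to queries <= 1000 nt")
    if max_breakpoints > 2:
        raise ValueError("oracle supports at most 2 breakpoints")
    costs = np.stack([
        _per_position_costs(query, parentA, **aln_kwargs),
        _per_position_costs(query, parentB, **aln_kwargs),
    ]).astype(float)
    n = costs.shape[1]
    pref = np.concatenate([np.zeros((2, 1)), np.cumsum(costs, axis=1)],
                          axis=1)

    def seg_cost(s: int, lo: int, hi: int) -> float:
        return pref[s, hi] - pref[s, lo]

    best: tuple[float, list[tuple[int, int, int]]] | None = None

    def consider(cost: float, segs: list[tuple[int, int, int]]) -> None:
        nonlocal best
        if best is None or cost < best[0] - 1e-12:
            best = (cost, segs)

    for s0 in (0, 1):
        consider(seg_cost(s0, 0, n), [(s0, 0, n)])
    if max_breakpoints >= 1:
        for s0 in (0, 1):
            mids = pref[s0, 1:n] + (pref[1 - s0, n] - pref[1 - s0, 1:n])
            p = int(np.argmin(mids)) + 1
            consider(float(mids[p - 1]) + sigma,
                     [(s0, 0, p), (1 - s0, p, n)])
    if max_breakpoints >= 2:
        for s0 in (0, 1):
            s1 = 1 - s0
            # cost(p, q) = s0[0:p] + s1[p:q] + s0[q:n], 1 <= p < q <= n
            for p in range(1, n - 1):
                qs = np.arange(p + 1, n)
                c = (pref[s0, p]
                     + (pref[s1, qs] - pref[s1, p])
                     + (pref[s0, n] - pref[s0, qs]))
                qi = int(np.argmin(c))
                consider(float(c[qi]) + 2 * sigma,
                         [(s0, 0, p), (s1, p, int(qs[qi])),
                          (s0, int(qs[qi]), n)])
    assert best is not None
    cost, segs = best
    labels = "".join("AB"[s] * (e - lo) for s, lo, e in segs)
    segments = [("AB"[s], lo, e) for s, lo, e in segs]
    bps = [lo for _, lo, _ in segments[1:]]
    return Segmentation(labels=labels, segments=segments, breakpoints=bps,
                        breakpoint_intervals=[(b, b) for b in bps],
                        total_cost=cost, n_switches=len(segments) - 1)
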