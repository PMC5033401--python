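"""Inversion-scenario search over signed block arrangements.

Two complementary routes:

* :func:`dimsum` — the stochastic search. Each replicate performs a random
  walk in arrangement space: inversion events are drawn uniformly from the
  n(n+1)/2 contiguous block intervals and applied sequentially, the walk
  stopping at the first arrangement equal to the target (under the
  configured equivalence) or after ``max_steps`` events. The event prefix
  up to the hit is recorded as a solution. Replicate ``r``'s random stream
  is derived deterministically from ``(seed, r)``, so results do not
  depend on execution order and reruns are bit-identical.

* :func:`exact_min_distance` / :func:`enumerate_minimal_scenarios` — an
  exact oracle: breadth-first search of the full signed-arrangement space
  (2^n * n! states), which certifies that a scenario is most parsimonious
  and can enumerate every minimal scenario. Practical for the block counts
  that arise in plastome work (n <= 8 by default).

:func:`breakpoint_count` provides the classical lower-bound diagnostic
(reversal distance >= ceil(breakpoints / 2)).

Because the replicate streams are independent of the arrangement being
sorted, one set of walks serves every possible target at once:
:func:`first_hit_lengths` exposes this all-targets view of the same walk
engine, used for exhaustive stochastic-vs-exact validation.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .arrangements import (
    InversionEvent,
    Scenario,
    SignedArrangement,
    relabel_against_reference,
)
from .errors import CapacityError, ConfigError

DEFAULT_EXACT_CAP = 8  # 2^8 * 8! ~ 10.3M states; plastome instances have n <= 3


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of a stochastic search run.

    ``replicates`` defaults to 10,000 — a desk-scale setting; published
    plastome analyses with this method used 1,000,000. ``max_steps`` is the
    per-replicate cap of 100 inversion events.
    """

    replicates: int = 10_000
    max_steps: int = 100
    seed: int = 0
    flip_equivalence: bool = False
    record_all_solutions: bool = True

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.max_steps < 1:
            raise ConfigError("max_steps must be >= 1")


@dataclass
class SearchResult:
    """Outcome of a stochastic search.

    ``solutions`` are deduplicated by exact event sequence;
    ``hits_by_length`` counts replicate hits *before* deduplication.
    ``exact_min`` is filled when the exact oracle has been consulted.
    """

    solutions: list[Scenario]
    min_length: int | None
    hits_by_length: dict[int, int]
    replicates_run: int
    config: SearchConfig
    exact_min: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "exact_min": self.exact_min,
            "min_length": self.min_length,
            "hits_by_length": {str(k): v for k, v in sorted(self.hits_by_length.items())},
            "replicates_run": self.replicates_run,
            "config": {
                "replicates": self.config.replicates,
                "max_steps": self.config.max_steps,
                "seed": self.config.seed,
                "flip_equivalence": self.config.flip_equivalence,
                "record_all_solutions": self.config.record_all_solutions,
            },
            "solutions": [
                [{"start": ev.start, "end": ev.end} for ev in sc.events]
                for sc in self.solutions
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_json_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def summary(self) -> str:
        lines = [
            f"replicates run      : {self.replicates_run}",
            f"minimum length found: {self.min_length}",
        ]
        if self.exact_min is not None:
            lines.append(f"exact minimum (BFS) : {self.exact_min}")
        total_hits = sum(self.hits_by_length.values())
        lines.append(
            f"replicates hitting  : {total_hits}"
            f" ({100.0 * total_hits / self.replicates_run:.1f}%)"
        )
        shown = sorted(self.hits_by_length)[:8]
        for length in shown:
            lines.append(f"  length {length:>3}: {self.hits_by_length[length]} hits")
        if len(self.hits_by_length) > len(shown):
            lines.append(f"  ... {len(self.hits_by_length) - len(shown)} more lengths")
        lines.append(f"distinct solutions  : {len(self.solutions)}")
        return "\n".join(lines)


def _intervals(n: int) -> list[tuple[int, int]]:
    """All n(n+1)/2 contiguous block intervals, 1-based inclusive."""
    return [(s, e) for s in range(1, n + 1) for e in range(s, n + 1)]


def _flip(t: tuple[int, ...]) -> tuple[int, ...]:
    """Whole-segment reverse complement of a signed tuple."""
    return tuple(-v for v in reversed(t))


def _replicate_draws(seed: int, replicates: int, max_steps: int, n_choices: int) -> np.ndarray:
    """Interval indices drawn per replicate, stream derived from (seed, r)."""
    out = np.empty((replicates, max_steps), dtype=np.int32)
    for r in range(replicates):
        rng = np.random.default_rng((seed, r))
        out[r] = rng.integers(0, n_choices, size=max_steps)
    return out


def _relabel(source: SignedArrangement, target: SignedArrangement):
    perm = relabel_against_reference(source, target)
    return len(perm.values), perm.values


class _WalkEngine:
    """Vectorised random walks shared by the single- and all-target views.

    States live in an int8 matrix of shape (replicates, n). Each step applies
    the replicate's drawn interval reversal in groups (one fancy-indexing
    pass per interval), which keeps the inner loop in numpy.
    """

    def __init__(self, n: int, cfg: SearchConfig):
        if n > 120:
            raise CapacityError("arrangements above 120 blocks are not supported")
        self.n = n
        self.cfg = cfg
        self.intervals = _intervals(n)
        self.draws = _replicate_draws(
            cfg.seed, cfg.replicates, cfg.max_steps, len(self.intervals)
        )

    def _initial(self) -> np.ndarray:
        ident = np.arange(1, self.n + 1, dtype=np.int8)
        return np.tile(ident, (self.cfg.replicates, 1))

    def _apply_step(self, state: np.ndarray, dj: np.ndarray, active: np.ndarray) -> None:
        for k, (s, e) in enumerate(self.intervals):
            rows = np.nonzero(active & (dj == k))[0]
            if rows.size:
                cols = np.arange(s - 1, e)
                state[np.ix_(rows, cols)] = -state[np.ix_(rows, cols)][:, ::-1]

    def first_hits(self, target: tuple[int, ...], flip: bool) -> np.ndarray:
        """Per-replicate step index of the first hit (-1 when never hit)."""
        state = self._initial()
        targets = [np.asarray(target, dtype=np.int8)]
        if flip and _flip(target) != target:
            targets.append(np.asarray(_flip(target), dtype=np.int8))

        def matches(st: np.ndarray) -> np.ndarray:
            eq = (st == targets[0]).all(axis=1)
            for t in targets[1:]:
                eq |= (st == t).all(axis=1)
            return eq

        hit = np.full(self.cfg.replicates, -1, dtype=np.int32)
        hit[matches(state)] = 0  # endpoint checked before the first event
        for j in range(1, self.cfg.max_steps + 1):
            active = hit < 0
            if not active.any():
                break
            self._apply_step(state, self.draws[:, j - 1], active)
            newly = active & matches(state)
            hit[newly] = j
        return hit

    def first_visit_lengths(self) -> dict[tuple[int, ...], int]:
        """First step at which each state is visited by any replicate.

        For every target ``t``, ``first_visit_lengths()[t]`` equals the
        ``min_length`` a single-target run against ``t`` would report,
        because walks are independent of the target and a replicate's first
        visit to ``t`` is exactly where that run would have stopped it.
        """
        n = self.n
        weights = (2 * n + 1) ** np.arange(n, dtype=np.int64)
        state = self._initial()
        first: dict[int, int] = {}

        def record(step: int) -> None:
            codes = ((state.astype(np.int64) + n) * weights).sum(axis=1)
            for c in np.unique(codes):
                first.setdefault(int(c), step)

        record(0)
        active = np.ones(self.cfg.replicates, dtype=bool)
        for j in range(1, self.cfg.max_steps + 1):
            self._apply_step(state, self.draws[:, j - 1], active)
            record(j)

        base = 2 * n + 1
        out: dict[tuple[int, ...], int] = {}
        for code, step in first.items():
            digits = []
            c = code
            for _ in range(n):
                digits.append(c % base - n)
                c //= base
            out[tuple(int(d) for d in digits)] = step
        return out


def dimsum(
    source: SignedArrangement,
    target: SignedArrangement,
    cfg: SearchConfig | None = None,
) -> SearchResult:
    """Stochastic search for inversion series transforming source into target.

    Runs ``cfg.replicates`` independent random walks (see module docstring)
    and reports every solution reached, the shortest length found, and the
    per-length replicate hit counts.
    """
    cfg = cfg or SearchConfig()
    n, target_t = _relabel(source, target)
    engine = _WalkEngine(n, cfg)
    hit = engine.first_hits(target_t, cfg.flip_equivalence)

    hits_by_length = dict(Counter(int(h) for h in hit if h >= 0))
    min_length = min(hits_by_length) if hits_by_length else None

    seen: set[tuple[tuple[int, int], ...]] = set()
    scenarios: list[Scenario] = []
    for r in np.nonzero(hit >= 0)[0]:
        length = int(hit[r])
        if not cfg.record_all_solutions and length != min_length:
            continue
        events = tuple(engine.intervals[k] for k in engine.draws[r, :length])
        if events not in seen:
            seen.add(events)
            scenarios.append(
                Scenario(source, tuple(InversionEvent(s, e) for s, e in events))
            )
    scenarios.sort(key=lambda sc: (len(sc.events), [(ev.start, ev.end) for ev in sc.events]))

    return SearchResult(
        solutions=scenarios,
        min_length=min_length,
        hits_by_length=hits_by_length,
        replicates_run=cfg.replicates,
        config=cfg,
    )


def first_hit_lengths(n: int, cfg: SearchConfig) -> dict[tuple[int, ...], int]:
    """All-targets view of the walk engine from the identity source.

    Returns, for every signed arrangement reached within ``cfg.max_steps``,
    the ``min_length`` the stochastic search would report against that
    target (without flip equivalence). States never visited are absent.
    """
    return _WalkEngine(n, cfg).first_visit_lengths()


# ---------------------------------------------------------------------------
# Exact oracle: BFS over the full signed-arrangement space
# ---------------------------------------------------------------------------


def _reverse_tuple(t: tuple[int, ...], s: int, e: int) -> tuple[int, ...]:
    return t[: s - 1] + tuple(-v for v in reversed(t[s - 1 : e])) + t[e:]


def _check_cap(n: int, cap: int) -> None:
    if n > cap:
        raise CapacityError(
            f"exact search capped at n={cap} blocks (requested n={n}); "
            "use the stochastic search for larger instances"
        )


def exact_min_distance(
    source: SignedArrangement,
    target: SignedArrangement,
    flip_equivalence: bool = False,
    cap: int = DEFAULT_EXACT_CAP,
) -> int:
    """Length of the shortest inversion series from source to target.

    Breadth-first search from the source over all signed arrangements;
    certifies parsimony of any scenario of the returned length.
    """
    n, target_t = _relabel(source, target)
    _check_cap(n, cap)
    start = tuple(range(1, n + 1))
    targets = {target_t}
    if flip_equivalence:
        targets.add(_flip(target_t))
    if start in targets:
        return 0
    intervals = _intervals(n)
    seen = {start}
    frontier = [start]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for st in frontier:
            for s, e in intervals:
                nb = _reverse_tuple(st, s, e)
                if nb in targets:
                    return d
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
    raise RuntimeError("arrangement space exhausted without reaching target")


def all_min_distances(n: int, cap: int = DEFAULT_EXACT_CAP) -> dict[tuple[int, ...], int]:
    """Exact distance from the identity to every signed arrangement of size n.

    One BFS pass over the whole space; by relabelling invariance this gives
    the distance for every source/target pair.
    """
    _check_cap(n, cap)
    start = tuple(range(1, n + 1))
    intervals = _intervals(n)
    dist = {start: 0}
    frontier = [start]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for st in frontier:
            for s, e in intervals:
                nb = _reverse_tuple(st, s, e)
                if nb not in dist:
                    dist[nb] = d
                    nxt.append(nb)
        frontier = nxt
    return dist


def enumerate_minimal_scenarios(
    source: SignedArrangement,
    target: SignedArrangement,
    flip_equivalence: bool = False,
    cap: int = DEFAULT_EXACT_CAP,
) -> list[Scenario]:
    """Every distinct minimal-length event series from source to target.

    BFS with predecessor tracking; output sorted by event sequence so the
    ordering is deterministic.
    """
    n, target_t = _relabel(source, target)
    _check_cap(n, cap)
    start = tuple(range(1, n + 1))
    targets = {target_t}
    if flip_equivalence:
        targets.add(_flip(target_t))
    intervals = _intervals(n)

    dist = {start: 0}
    parents: dict[tuple[int, ...], list] = {start: []}
    level = [start]
    d = 0
    found = targets & {start}
    while level and not found:
        d += 1
        nxt: list[tuple[int, ...]] = []
        for st in level:
            for s, e in intervals:
                nb = _reverse_tuple(st, s, e)
                if nb in dist:
                    if dist[nb] == d:
                        parents[nb].append((st, (s, e)))
                    continue
                dist[nb] = d
                parents[nb] = [(st, (s, e))]
                nxt.append(nb)
        level = nxt
        found = targets & set(level)
        found = {t for t in found if dist[t] == d}

    event_lists: list[tuple[tuple[int, int], ...]] = []

    def backtrack(state: tuple[int, ...], suffix: tuple[tuple[int, int], ...]) -> None:
        if state == start and not suffix and dist[state] == 0:
            pass
        if dist[state] == 0:
            event_lists.append(suffix)
            return
        for prev, ev in parents[state]:
            backtrack(prev, (ev,) + suffix)

    for t in sorted(found):
        backtrack(t, ())

    unique = sorted(set(event_lists))
    return [
        Scenario(source, tuple(InversionEvent(s, e) for s, e in events))
        for events in unique
    ]


def breakpoint_count(source: SignedArrangement, target: SignedArrangement) -> int:
    """Signed breakpoints between the two arrangements (with end terminals).

    In the source's identity frame, an adjacency ``(a, b)`` of the extended
    target ``(0, pi_1, ..., pi_n, n+1)`` is conserved iff ``b - a == 1``.
    ``exact_min_distance >= ceil(breakpoint_count / 2)`` always holds, since
    one inversion can remove at most two breakpoints.
    """
    n, target_t = _relabel(source, target)
    ext = (0,) + target_t + (n + 1,)
    return sum(1 for a, b in zip(ext, ext[1:]) if b - a != 1)
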