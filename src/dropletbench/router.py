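"""Merge-free routing of droplets to designated electrodes.

After single-cell droplets are identified, each must reach a designated
target electrode without ever coming close enough to another droplet to
merge.  Assignment is the minimum-total-Manhattan-distance bipartite
matching; paths come from prioritized space-time A* — droplets are planned
longest-distance first against a reservation table holding the trajectories
of already-planned droplets, with waits allowed and a bounded
priority-rotation retry on deadlock.  The separation constraint is a
Chebyshev distance of at least ``min_separation`` between every droplet
pair at every synchronized time step (the default of 2 rules out
8-adjacency, the merge condition of the grid droplet model).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from dropletbench.synth import GridSpec

__all__ = ["RoutingProblem", "RoutePlan", "assign_targets", "plan_routes", "validate_plan"]

Coord = tuple[int, int]


@dataclass(frozen=True)
class RoutingProblem:
    grid: GridSpec
    sources: tuple[Coord, ...]
    targets: tuple[Coord, ...]
    min_separation: int = 2
    obstacles: frozenset[Coord] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.sources) != len(self.targets):
            raise ValueError("need exactly one target per source")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")
        for name, coords in (("source", self.sources), ("target", self.targets), ("obstacle", self.obstacles)):
            for c, r in coords:
                if not (0 <= c < self.grid.n_cols and 0 <= r < self.grid.n_rows):
                    raise ValueError(f"{name} ({c}, {r}) is off-grid")
        for group, name in ((self.sources, "sources"), (self.targets, "targets")):
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    if _cheb(group[i], group[j]) < self.min_separation:
                        raise ValueError(f"{name} {i} and {j} closer than min_separation")


@dataclass
class RoutePlan:
    assignment: tuple[int, ...]  # assignment[i] = target index of source i
    paths: tuple[tuple[Coord, ...], ...]  # per source, one electrode per step (incl. endpoints)
    makespan: int


def _cheb(a: Coord, b: Coord) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def _manhattan(a: Coord, b: Coord) -> int:
    return abs(a[0] - b[0]) + abs(a[1] - b[1])


def assign_targets(problem: RoutingProblem) -> tuple[int, ...]:
    """Minimum-total-Manhattan-distance source-to-target assignment.

    Deterministic: among optimal assignments, ties break toward lower
    (source index, target index) pairs.
    """
    n = len(problem.sources)
    if n == 0:
        return ()
    cost = np.zeros((n, n))
    for i, s in enumerate(problem.sources):
        for j, t in enumerate(problem.targets):
            cost[i, j] = _manhattan(s, t) + (i * n + j) * 1e-9  # deterministic tie-break
    rows, cols = linear_sum_assignment(cost)
    assignment = [0] * n
    for i, j in zip(rows, cols):
        assignment[i] = int(j)
    return tuple(assignment)


def plan_routes(
    problem: RoutingProblem,
    assignment: tuple[int, ...] | None = None,
    max_retries: int = 8,
) -> RoutePlan:
    """Plan merge-free synchronized paths realizing the assignment.

    Prioritized planning: droplets are routed one at a time in descending
    Manhattan-distance order, each by space-time A* (4-neighbour moves or
    wait) against the reservation of already-planned trajectories; a
    droplet parks at its target after arrival.  On failure the priority
    order is rotated up to ``max_retries`` times before reporting the
    blocking pair.
    """
    if assignment is None:
        assignment = assign_targets(problem)
    n = len(problem.sources)
    if n == 0:
        return RoutePlan(assignment=(), paths=(), makespan=0)
    base_order = sorted(
        range(n), key=lambda i: (-_manhattan(problem.sources[i], problem.targets[assignment[i]]), i)
    )
    horizon = sum(_manhattan(problem.sources[i], problem.targets[assignment[i]]) for i in range(n))
    horizon += 4 * (problem.grid.n_cols + problem.grid.n_rows) + 8 * n

    last_failure: tuple[int, int | None] = (base_order[0], None)
    for rot in range(max_retries + 1):
        order = base_order[rot % n :] + base_order[: rot % n]
        paths: dict[int, tuple[Coord, ...]] = {}
        ok = True
        for i in order:
            path = _space_time_astar(
                problem, problem.sources[i], problem.targets[assignment[i]], paths, horizon
            )
            if path is None:
                ok = False
                blocker = next(iter(paths)) if paths else None
                last_failure = (i, blocker)
                break
            paths[i] = path
        if ok:
            makespan = max(len(p) - 1 for p in paths.values())
            return RoutePlan(
                assignment=tuple(assignment),
                paths=tuple(paths[i] for i in range(n)),
                makespan=makespan,
            )
    i, j = last_failure
    raise RuntimeError(
        f"routing failed within the step budget: droplet {i} could not reach its target"
        + (f" (first-planned droplet {j} blocks it)" if j is not None else "")
    )


def _pos_at(path: tuple[Coord, ...], t: int) -> Coord:
    return path[t] if t < len(path) else path[-1]


def _space_time_astar(
    problem: RoutingProblem,
    start: Coord,
    goal: Coord,
    reserved: dict[int, tuple[Coord, ...]],
    horizon: int,
) -> tuple[Coord, ...] | None:
    sep = problem.min_separation
    park_until = max((len(p) - 1 for p in reserved.values()), default=0)

    def feasible(pos: Coord, t: int) -> bool:
        if pos in problem.obstacles:
            return False
        return all(_cheb(pos, _pos_at(p, t)) >= sep for p in reserved.values())

    def goal_clear(t: int) -> bool:
        # once parked, the droplet must stay clear of every later reserved position
        return all(
            _cheb(goal, _pos_at(p, tt)) >= sep
            for p in reserved.values()
            for tt in range(t, park_until + 1)
        )

    if not feasible(start, 0):
        return None
    open_heap: list[tuple[int, int, int, Coord]] = [(_manhattan(start, goal), 0, 0, start)]
    came: dict[tuple[Coord, int], tuple[Coord, int]] = {}
    seen = {(start, 0)}
    counter = 0
    while open_heap:
        _, _, t, pos = heapq.heappop(open_heap)
        if pos == goal and goal_clear(t):
            node = (pos, t)
            rev = [pos]
            while node in came:
                node = came[node]
                rev.append(node[0])
            return tuple(reversed(rev))
        if t >= horizon:
            continue
        c, r = pos
        for nxt in ((c, r), (c + 1, r), (c - 1, r), (c, r + 1), (c, r - 1)):
            if not (0 <= nxt[0] < problem.grid.n_cols and 0 <= nxt[1] < problem.grid.n_rows):
                continue
            if (nxt, t + 1) in seen or not feasible(nxt, t + 1):
                continue
            seen.add((nxt, t + 1))
            came[(nxt, t + 1)] = (pos, t)
            counter += 1
            heapq.heappush(open_heap, (t + 1 + _manhattan(nxt, goal), counter, t + 1, nxt))
    return None


def validate_plan(plan: RoutePlan, problem: RoutingProblem) -> list[str]:
    """Replay a plan step-synchronously and list every constraint violation.

    Checks path continuity (4-neighbour moves or stays), endpoints,
    obstacle avoidance, and the pairwise separation at every time step.
    An empty list means the plan is sound.
    """
    violations: list[str] = []
    n = len(plan.paths)
    if n != len(problem.sources):
        violations.append(f"plan has {n} paths for {len(problem.sources)} sources")
        return violations
    for i, path in enumerate(plan.paths):
        if not path:
            violations.append(f"droplet {i}: empty path")
            continue
        if path[0] != problem.sources[i]:
            violations.append(f"droplet {i}: path starts at {path[0]}, not its source")
        if path[-1] != problem.targets[plan.assignment[i]]:
            violations.append(f"droplet {i}: path ends at {path[-1]}, not its target")
        for t in range(1, len(path)):
            if _manhattan(path[t - 1], path[t]) > 1:
                violations.append(f"droplet {i}: illegal move {path[t - 1]} -> {path[t]} at t={t}")
    span = max((len(p) - 1 for p in plan.paths), default=0)
    if span != plan.makespan:
        violations.append(f"declared makespan {plan.makespan} != realized {span}")
    for t in range(span + 1):
        positions = [_pos_at(p, t) for p in plan.paths]
        for i, pos in enumerate(positions):
            if pos in problem.obstacles:
                violations.append(f"droplet {i} on obstacle {pos} at t={t}")
        for i in range(n):
            for j in range(i + 1, n):
                if _cheb(positions[i], positions[j]) < problem.min_separation:
                    violations.append(f"droplets {i} and {j} violate separation at t={t}")
    return violations
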