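"""Exact bi-objective solving by parallel two-phase rectangle splitting.

Both objectives are minimized. A nondominated point inside an
objective-space rectangle is obtained by lexicographic minimization (lexmin):
minimize the primary objective, then the secondary subject to the primary
staying at its optimum (within delta). Phase 1 seeds the front by slicing
the z1 range between the two boundary points into m even sections; phase 2
recursively splits the rectangle spanned by each pair of adjacent known
points in half along z2, closing a rectangle once its corner points are
rediscovered. Rectangles are independent work items, so the front is
invariant to the number of workers and to processing order.

Numerical contract: upper bounds on both objectives and lower bounds on z2
are enforced exactly in the MILP; lower bounds on z1 cannot be expressed
exactly through the hinge slacks and are dropped — they are redundant
whenever the rectangle corners are nondominated, which the algorithm
maintains. Front points closer than eps in z1 (or delta in z2) may merge;
both tolerances are configurable.
"""

from __future__ import annotations

import threading
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .ilp import DesignProblem, IlpInstance, SolutionPoint, build_instance
from .epitopes import immunogenicity_score
from .potts import statistical_energy

DELTA = 1e-6
EPS = 1e-6


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned search box spanned by two objective-space points:
    corner1 = (z1 low, z2 high), corner2 = (z1 high, z2 low)."""

    corner1: tuple[float, float]
    corner2: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.corner1[0] <= self.corner2[0] and
                self.corner2[1] <= self.corner1[1]):
            raise ValueError(f"invalid rectangle {self.corner1} .. {self.corner2}")

    @classmethod
    def unbounded(cls) -> "Rectangle":
        return cls((-np.inf, np.inf), (np.inf, -np.inf))


@dataclass
class ParetoFront:
    """Nondominated points sorted by increasing z1 (hence decreasing z2)."""

    points: list[SolutionPoint]
    stats: dict = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def objectives(self) -> np.ndarray:
        return np.array([p.z for p in self.points])


def _close(a: tuple[float, float], b: tuple[float, float],
           delta: float = DELTA) -> bool:
    return abs(a[0] - b[0]) <= delta and abs(a[1] - b[1]) <= delta


def lexmin(instance: IlpInstance, primary: str, rect: Rectangle | None = None,
           delta: float = DELTA) -> SolutionPoint | None:
    """Two-stage lexicographic minimization inside ``rect``.

    Returns None when the rectangle contains no feasible point. The second
    stage is feasible by construction whenever the first is; this is
    asserted, not silently repaired.
    """
    if rect is None:
        rect = Rectangle.unbounded()
    z1_max, z2_min = rect.corner2
    z1_min, z2_max = rect.corner1  # z1_min intentionally unused (see module docstring)
    first = instance.solve_single(primary, z1_max=z1_max, z2_max=z2_max,
                                  z2_min=z2_min)
    if not first.feasible:
        return None
    secondary = "z2" if primary == "z1" else "z1"
    opt = first.z[0] if primary == "z1" else first.z[1]
    second = instance.solve_single(secondary, z1_max=z1_max, z2_max=z2_max,
                                   z2_min=z2_min,
                                   extra_bound=(primary, opt + delta))
    assert second.feasible, "stage 2 infeasible after feasible stage 1"
    return second


def compute_boundaries(instance: IlpInstance,
                       delta: float = DELTA) -> tuple[SolutionPoint, SolutionPoint]:
    """Front endpoints: z_T = lexmin(z1, z2), z_B = lexmin(z2, z1), both
    over the unbounded rectangle. The two solves are independent."""
    z_t = lexmin(instance, "z1", None, delta)
    z_b = lexmin(instance, "z2", None, delta)
    if z_t is None or z_b is None:
        raise ValueError("design problem is infeasible")
    return z_t, z_b


def phase1_slices(instance: IlpInstance, z_t: SolutionPoint, z_b: SolutionPoint,
                  m: int, delta: float = DELTA,
                  workers: int = 1) -> list[SolutionPoint]:
    """Even initial approximation of the front.

    The z1 range [z1_T, z1_B] is cut at m boundaries tau_i; for each, the
    nondominated point with the largest z1 not exceeding tau_i is found by
    lexmin with z2 as the primary objective under the exact constraint
    z1 <= tau_i. Every returned point is nondominated; duplicates are merged
    at delta tolerance. The output always contains z_B (the i = m slice).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    lo, hi = z_t.z[0], z_b.z[0]
    taus = [lo + i * (hi - lo) / m for i in range(1, m + 1)]

    def solve(tau: float) -> SolutionPoint | None:
        rect = Rectangle((-np.inf, z_t.z[1] + delta), (tau, z_b.z[1] - delta))
        return lexmin(instance, "z2", rect, delta)

    if workers > 1 and len(taus) > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(solve, taus))
    else:
        results = [solve(t) for t in taus]
    return _merge_points([p for p in results if p is not None], delta)


def split_rectangle(instance: IlpInstance, z_i: SolutionPoint, z_j: SolutionPoint,
                    delta: float = DELTA, eps: float = EPS
                    ) -> tuple[list[SolutionPoint], list[tuple[SolutionPoint, SolutionPoint]]]:
    """Search the open rectangle between adjacent nondominated points.

    The bottom half (z2 <= midline) is searched z1-first; if it contains a
    new point, the top half is restricted to z1 <= that point's z1 - eps and
    searched z2-first. Rediscovering the corners proves the corresponding
    half empty. Returns (new points, child rectangles as point pairs).
    """
    (z1_i, z2_i), (z1_j, z2_j) = z_i.z, z_j.z
    if z1_j - z1_i <= eps or z2_i - z2_j <= delta:
        return [], []
    mid = 0.5 * (z2_i + z2_j)

    bottom = lexmin(instance, "z1",
                    Rectangle((-np.inf, mid), (z1_j + delta, z2_j - delta)), delta)
    assert bottom is not None, "bottom half must contain its corner point"
    b_new = None if _close(bottom.z, z_j.z, delta) else bottom
    zbar1 = (b_new or z_j).z[0]

    top_rect_hi = zbar1 - eps
    t_new = None
    if top_rect_hi > z1_i - delta:
        top = lexmin(instance, "z2",
                     Rectangle((-np.inf, z2_i + delta), (top_rect_hi, mid - delta)),
                     delta)
        if top is not None and not _close(top.z, z_i.z, delta):
            t_new = top

    new_points: list[SolutionPoint] = []
    children: list[tuple[SolutionPoint, SolutionPoint]] = []
    if t_new is not None:
        new_points.append(t_new)
        children.append((z_i, t_new))
    if b_new is not None:
        new_points.append(b_new)
        children.append((b_new, z_j))
    return new_points, children


def solve_pareto(instance_or_problem, m: int = 4, workers: int = 1,
                 delta: float = DELTA, eps: float = EPS) -> ParetoFront:
    """Compute the full exact Pareto front of a design instance.

    ``m`` controls the phase-1 slicing granularity (the paper's even split
    of the z1 range); ``workers`` parallelizes independent rectangles and
    slices without affecting the result.
    """
    if isinstance(instance_or_problem, DesignProblem):
        instance = build_instance(instance_or_problem)
    else:
        instance = instance_or_problem

    z_t, z_b = compute_boundaries(instance, delta)
    lex_calls = [2]
    lock = threading.Lock()
    if _close(z_t.z, z_b.z, delta):
        return ParetoFront(points=[z_t],
                           stats={"lexmin_calls": 2,
                                  "milp_solves": instance.stats["milp_solves"],
                                  "rectangles": 0})

    front = _merge_points([z_t] + phase1_slices(instance, z_t, z_b, m, delta,
                                                workers), delta)
    lex_calls[0] += m
    phase1_len = len(front)

    queue = list(zip(front[:-1], front[1:]))
    n_rect = 0
    while queue:
        n_rect += len(queue)

        def work(pair):
            res = split_rectangle(instance, pair[0], pair[1], delta, eps)
            with lock:
                lex_calls[0] += 2
            return res

        if workers > 1 and len(queue) > 1:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                results = list(pool.map(work, queue))
        else:
            results = [work(pair) for pair in queue]
        new_pts = [p for pts, _ in results for p in pts]
        queue = [c for _, children in results for c in children]
        front = _merge_points(front + new_pts, delta)

    front = _merge_points(front, delta)
    _assert_front(front, delta)
    return ParetoFront(points=front,
                       stats={"lexmin_calls": lex_calls[0],
                              "milp_solves": instance.stats["milp_solves"],
                              "rectangles": n_rect,
                              "phase1_points": phase1_len})


def brute_force_pareto(problem: DesignProblem, limit: int = 200_000,
                       delta: float = DELTA) -> ParetoFront:
    """Independent oracle: enumerate every mutant within Hamming distance k
    of the wild type, evaluate both objectives directly on the sequences and
    extract the nondominated set."""
    from itertools import combinations, product

    M = problem.mutation_sets.M
    wt = problem.wild_type
    mutable = [i for i in range(problem.n) if len(M[i]) > 1]
    alts = {i: [a for a in M[i] if a != wt[i]] for i in mutable}

    total = 0
    for r in range(min(problem.k, len(mutable)) + 1):
        for combo in combinations(mutable, r):
            c = 1
            for i in combo:
                c *= len(alts[i])
            total += c
    if total > limit:
        raise ValueError(f"search space {total} exceeds limit {limit}")

    cand: list[tuple[float, float, str]] = []
    for r in range(min(problem.k, len(mutable)) + 1):
        for combo in combinations(mutable, r):
            for choice in product(*(alts[i] for i in combo)):
                seq = list(wt)
                for i, a in zip(combo, choice):
                    seq[i] = a
                s = "".join(seq)
                z1 = immunogenicity_score(s, problem.population)
                z2 = -statistical_energy(problem.potts, s)
                cand.append((z1, z2, s))

    cand.sort(key=lambda t: (t[0], t[1]))
    front: list[tuple[float, float, str]] = []
    best_z2 = np.inf
    for z1, z2, s in cand:
        if z2 < best_z2 - delta:
            if front and abs(front[-1][0] - z1) <= delta:
                front[-1] = (z1, z2, s)  # same z1 (within delta): keep min z2
            else:
                front.append((z1, z2, s))
            best_z2 = z2
    points = [
        SolutionPoint(z=(z1, z2), sequence=s,
                      mutations=[(problem.offset + i, wt[i], s[i])
                                 for i in range(problem.n) if s[i] != wt[i]],
                      status="optimal")
        for z1, z2, s in front]
    return ParetoFront(points=points, stats={"candidates": total})


def _merge_points(points: list[SolutionPoint], delta: float) -> list[SolutionPoint]:
    """Sort by z1, drop duplicates (within delta) and dominated points."""
    pts = sorted(points, key=lambda p: (p.z[0], p.z[1]))
    out: list[SolutionPoint] = []
    for p in pts:
        if out and _close(p.z, out[-1].z, delta):
            continue
        # sorted by z1, so p is dominated iff the last kept point (the one
        # with the smallest z2 so far) does not beat it in z2
        if out and out[-1].z[1] <= p.z[1] + delta:
            continue
        out.append(p)
    return out


def _assert_front(points: list[SolutionPoint], delta: float) -> None:
    z = np.array([p.z for p in points])
    if len(z) > 1:
        assert np.all(np.diff(z[:, 0]) > 0), "front z1 not strictly increasing"
        assert np.all(np.diff(z[:, 1]) < 0), "front z2 not strictly decreasing"
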