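"""Pareto solver tests on an enumerable fake backend and on real MILP toys.

The FakeInstance emulates `solve_single` over an explicit finite point set
with the same bound semantics as the MILP (exact upper bounds on both
objectives, exact lower bound on z2, relaxed lower bound on z1), which lets
the lexmin / slicing / splitting logic be checked against hand-enumerable
fronts independently of the MILP layer.
"""

import numpy as np
import pytest

import deimmune as dm
from deimmune.ilp import SolutionPoint
from deimmune.pareto import Rectangle, _merge_points


class FakeInstance:
    def __init__(self, points):
        self.points = [tuple(map(float, p)) for p in points]
        self.stats = {"milp_solves": 0}

    def solve_single(self, objective, z1_max=np.inf, z1_min=-np.inf,
                     z2_max=np.inf, z2_min=-np.inf, extra_bound=None):
        self.stats["milp_solves"] += 1
        feas = [p for p in self.points
                if p[0] <= z1_max + 1e-12 and p[1] <= z2_max + 1e-12
                and p[1] >= z2_min - 1e-12]
        if extra_bound is not None:
            obj, val = extra_bound
            idx = 0 if obj == "z1" else 1
            feas = [p for p in feas if p[idx] <= val + 1e-12]
        if not feas:
            return SolutionPoint(z=(np.nan, np.nan), sequence="",
                                 mutations=[], status="infeasible")
        idx = 0 if objective == "z1" else 1
        best = min(feas, key=lambda p: (p[idx], p[1 - idx]))
        return SolutionPoint(z=best, sequence=f"{best}", mutations=[],
                             status="optimal")


TOY = [(1, 5), (2, 3), (4, 1)]  # a simple strictly-decreasing front
CLOUD = TOY + [(1.5, 6), (3, 4), (5, 2), (4.5, 5)]  # adds dominated points


def enumerate_front(points):
    pts = sorted(points)
    front, best = [], np.inf
    for z1, z2 in pts:
        if z2 < best:
            front.append((z1, z2))
            best = z2
    return front


class TestLexmin:
    def test_primary_z1_finds_left_end(self):
        pt = dm.lexmin(FakeInstance(CLOUD), "z1")
        assert pt.z == (1, 5)

    def test_primary_z2_finds_right_end(self):
        pt = dm.lexmin(FakeInstance(CLOUD), "z2")
        assert pt.z == (4, 1)

    def test_rectangle_with_single_point(self):
        inst = FakeInstance(CLOUD)
        rect = Rectangle((1.9, 3.5), (2.1, 2.5))
        assert dm.lexmin(inst, "z1", rect).z == (2, 3)

    def test_empty_rectangle_returns_none(self):
        rect = Rectangle((-np.inf, 0.5), (0.5, -np.inf))
        assert dm.lexmin(FakeInstance(CLOUD), "z1", rect) is None

    def test_lexmin_breaks_ties_toward_nondominance(self):
        # two points share minimal z1; stage 2 must pick the lower z2
        inst = FakeInstance([(1, 5), (1, 2), (3, 1)])
        assert dm.lexmin(inst, "z1").z == (1, 2)


class TestBoundaries:
    def test_single_point_universe(self):
        z_t, z_b = dm.compute_boundaries(FakeInstance([(2, 2)]))
        assert z_t.z == z_b.z == (2, 2)

    def test_toy_front_endpoints(self):
        z_t, z_b = dm.compute_boundaries(FakeInstance(CLOUD))
        assert z_t.z == (1, 5) and z_b.z == (4, 1)

    def test_infeasible_instance_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            dm.compute_boundaries(FakeInstance([]))


class TestPhase1:
    def test_m1_recovers_bottom_boundary_only(self):
        inst = FakeInstance(CLOUD)
        z_t, z_b = dm.compute_boundaries(inst)
        pts = dm.phase1_slices(inst, z_t, z_b, m=1)
        assert [p.z for p in pts] == [(4, 1)]

    def test_m_at_front_size_recovers_full_front(self):
        inst = FakeInstance(CLOUD)
        z_t, z_b = dm.compute_boundaries(inst)
        pts = dm.phase1_slices(inst, z_t, z_b, m=4)
        assert [p.z for p in pts] == TOY

    def test_no_dominated_point_ever_returned(self):
        rng = np.random.default_rng(0)
        cloud = [(float(a), float(b)) for a, b in rng.uniform(0, 10, (40, 2))]
        inst = FakeInstance(cloud)
        z_t, z_b = dm.compute_boundaries(inst)
        front = set(enumerate_front(cloud))
        for m in (1, 2, 3, 7):
            pts = dm.phase1_slices(inst, z_t, z_b, m=m)
            assert {p.z for p in pts} <= front


class TestSplitRectangle:
    def test_empty_gap_closes_without_new_points(self):
        inst = FakeInstance(CLOUD)
        z_i = SolutionPoint(z=(1.0, 5.0), sequence="", mutations=[], status="optimal")
        z_j = SolutionPoint(z=(2.0, 3.0), sequence="", mutations=[], status="optimal")
        new, children = dm.split_rectangle(inst, z_i, z_j)
        assert new == [] and children == []

    def test_hidden_interior_point_is_found(self):
        inst = FakeInstance(CLOUD)
        z_i = SolutionPoint(z=(1.0, 5.0), sequence="", mutations=[], status="optimal")
        z_j = SolutionPoint(z=(4.0, 1.0), sequence="", mutations=[], status="optimal")
        new, children = dm.split_rectangle(inst, z_i, z_j)
        assert [p.z for p in new] == [(2.0, 3.0)]
        # the top half is proven empty (corner rediscovered), so only the
        # rectangle between the new point and z_j remains open
        assert [(a.z, b.z) for a, b in children] == [((2.0, 3.0), (4.0, 1.0))]

    def test_degenerate_rectangle_closed_immediately(self):
        inst = FakeInstance(CLOUD)
        z = SolutionPoint(z=(2.0, 3.0), sequence="", mutations=[], status="optimal")
        assert dm.split_rectangle(inst, z, z) == ([], [])


class TestSolveParetoFake:
    @pytest.mark.parametrize("m", [1, 2, 5])
    def test_random_clouds_match_enumeration(self, m):
        rng = np.random.default_rng(1)
        for _ in range(10):
            cloud = [(float(a), float(b)) for a, b in rng.uniform(0, 10, (30, 2))]
            front = dm.solve_pareto(FakeInstance(cloud), m=m)
            assert [p.z for p in front.points] == enumerate_front(cloud)

    def test_single_point_front(self):
        front = dm.solve_pareto(FakeInstance([(3, 3), (4, 4)]))
        assert [p.z for p in front.points] == [(3, 3)]


class TestSolveParetoReal:
    def test_front_matches_brute_force(self, toy_problem):
        milp = dm.solve_pareto(toy_problem, m=3)
        bf = dm.brute_force_pareto(toy_problem)
        assert np.allclose(milp.objectives(), bf.objectives(), atol=1e-6)

    def test_front_sorted_and_mutually_nondominated(self, toy_problem):
        z = dm.solve_pareto(toy_problem, m=3).objectives()
        assert np.all(np.diff(z[:, 0]) > 0)
        assert np.all(np.diff(z[:, 1]) < 0)

    def test_worker_invariance(self, toy_problem):
        f1 = dm.solve_pareto(toy_problem, m=3, workers=1)
        f4 = dm.solve_pareto(toy_problem, m=3, workers=4)
        assert np.allclose(f1.objectives(), f4.objectives(), atol=1e-9)

    def test_every_point_objective_verified(self, toy_problem):
        front = dm.solve_pareto(toy_problem, m=3)
        for p in front.points:
            assert p.z[0] == pytest.approx(
                dm.immunogenicity_score(p.sequence, toy_problem.population),
                abs=1e-6)
            assert p.z[1] == pytest.approx(
                -dm.statistical_energy(toy_problem.potts, p.sequence), abs=1e-6)


class TestBruteForce:
    def test_k0_gives_wild_type_only(self, toy_problem):
        prob = dm.DesignProblem(wild_type=toy_problem.wild_type,
                                mutation_sets=toy_problem.mutation_sets, k=0,
                                population=toy_problem.population,
                                potts=toy_problem.potts)
        front = dm.brute_force_pareto(prob)
        assert len(front.points) == 1
        assert front.points[0].sequence == prob.wild_type

    def test_candidate_count_small_k1(self, toy_problem):
        prob = dm.DesignProblem(wild_type=toy_problem.wild_type,
                                mutation_sets=toy_problem.mutation_sets, k=1,
                                population=toy_problem.population,
                                potts=toy_problem.potts)
        front = dm.brute_force_pareto(prob)
        n_alts = sum(len(m) - 1 for m in prob.mutation_sets.M)
        assert front.stats["candidates"] == 1 + n_alts

    def test_limit_exceeded_raises(self, toy_problem):
        with pytest.raises(ValueError, match="exceeds limit"):
            dm.brute_force_pareto(toy_problem, limit=2)


class TestMergePoints:
    def test_duplicates_and_dominated_removed(self):
        def sp(z):
            return SolutionPoint(z=z, sequence="", mutations=[], status="optimal")
        pts = [sp((1, 5)), sp((1 + 1e-9, 5)), sp((2, 6)), sp((2, 3)), sp((4, 1))]
        merged = _merge_points(pts, delta=1e-6)
        assert [p.z for p in merged] == [(1, 5), (2, 3), (4, 1)]
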