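"""Mixed-integer encoding of the bi-objective design problem.

Variables: one binary x_{i,a} per mutable position i and allowed residue a;
one continuous pairing variable w_{i,j,a,b} per residue pair of a mutable
position pair (forced to x_{i,a} * x_{j,b} by the linking constraints, so it
may stay continuous); one continuous slack y_{h,win} per (allele, window)
whose hinge depends on at least one variable position.

Objectives: z1 is the population immunogenicity (hinge slacks plus the
constant contribution of windows not touching any mutable position); z2 is
the negated Potts statistical energy -E(S'), so both objectives are
minimized. Field and coupling terms of immutable positions are folded into
constants and linear coefficients, which keeps reported z2 a full-sequence
quantity comparable across designs.

The solver backend is HiGHS through ``scipy.optimize.milp`` with a zero MIP
gap, i.e. proven-optimal solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .epitopes import Population, immunogenicity_score
from .msa import MutationSets
from .potts import PottsModel, statistical_energy


@dataclass
class DesignProblem:
    """A de-immunization instance: wild type, substitution sets, mutation
    load k, target population and the family Potts model."""

    wild_type: str
    mutation_sets: MutationSets
    k: int
    population: Population
    potts: PottsModel
    offset: int = 1  # protein numbering of position 1

    def __post_init__(self) -> None:
        n = len(self.wild_type)
        if self.mutation_sets.n != n:
            raise ValueError("mutation sets length disagrees with wild type")
        if self.potts.L != n:
            raise ValueError("Potts model length disagrees with wild type")
        if self.k < 0:
            raise ValueError("mutation load k must be >= 0")
        if self.mutation_sets.wild_type != self.wild_type:
            raise ValueError("mutation sets were built for a different wild type")

    @property
    def n(self) -> int:
        return len(self.wild_type)


@dataclass
class SolutionPoint:
    z: tuple[float, float]
    sequence: str
    mutations: list[tuple[int, str, str]]  # (protein-numbered position, wt, new)
    status: str  # "optimal" | "infeasible"

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


@dataclass
class IlpInstance:
    problem: DesignProblem
    relax_linking: bool = False

    # filled by _build
    x_index: dict = field(default_factory=dict, repr=False)
    w_index: dict = field(default_factory=dict, repr=False)
    y_index: dict = field(default_factory=dict, repr=False)
    n_vars: int = 0
    integrality: np.ndarray | None = None
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None
    c1: np.ndarray | None = None  # z1 linear part (over y slacks)
    c2: np.ndarray | None = None  # z2 linear part (over x, w)
    const1: float = 0.0
    const2: float = 0.0
    A_eq: sp.csr_matrix | None = None
    b_eq: np.ndarray | None = None
    A_ub: sp.csr_matrix | None = None
    b_ub: np.ndarray | None = None
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._build()

    # -- construction -----------------------------------------------------

    def _build(self) -> None:
        prob = self.problem
        n = prob.n
        M = prob.mutation_sets.M
        pop = prob.population
        model = prob.potts
        for allele in pop.alleles:
            if allele.tau is None:
                raise ValueError(f"allele {allele.name} has no binding threshold")
        aidx = {c: i for i, c in enumerate(model.alphabet)}
        wt_codes = [aidx[c] for c in prob.wild_type]

        mutable = [i for i in range(n) if len(M[i]) > 1]
        self.mutable = mutable
        var = 0
        for i in mutable:
            for a in M[i]:
                self.x_index[(i, a)] = var
                var += 1
        for ii, i in enumerate(mutable):
            for j in mutable[ii + 1:]:
                for a in M[i]:
                    for b in M[j]:
                        self.w_index[(i, j, a, b)] = var
                        var += 1
        e_n = pop.e_n if pop.alleles else 1
        n_windows = n - e_n + 1
        if pop.alleles and n_windows < 1:
            raise ValueError("sequence shorter than the binding core")
        mut_set = set(mutable)
        var_windows = [w for w in range(n_windows)
                       if any((w + j) in mut_set for j in range(e_n))]
        for allele in pop.alleles:
            for w in var_windows:
                self.y_index[(allele.name, w)] = var
                var += 1
        self.n_vars = var

        self.integrality = np.zeros(var)
        self.lb = np.zeros(var)
        self.ub = np.full(var, np.inf)
        for idx in self.x_index.values():
            self.integrality[idx] = 1
            self.ub[idx] = 1.0
        for idx in self.w_index.values():
            self.ub[idx] = 1.0

        # ---- z2 = -E(S'): constants, linear and pairwise coefficients
        const_E = 0.0
        c2 = np.zeros(var)
        for i in range(n):
            if i not in mut_set:
                const_E += model.h[i, wt_codes[i]]
        for i in range(n):
            for j in range(i + 1, n):
                if i not in mut_set and j not in mut_set:
                    const_E += model.J[i, j, wt_codes[i], wt_codes[j]]
        for i in mutable:
            for a in M[i]:
                coef = model.h[i, aidx[a]]
                for j in range(n):
                    if j != i and j not in mut_set:
                        coef += model.J[i, j, aidx[a], wt_codes[j]]
                c2[self.x_index[(i, a)]] = -coef
        for (i, j, a, b), idx in self.w_index.items():
            c2[idx] = -model.J[i, j, aidx[a], aidx[b]]
        self.c2 = c2
        self.const2 = -const_E

        # ---- z1: hinge slacks + constant windows
        c1 = np.zeros(var)
        const1 = 0.0
        hinge_rows: list[tuple[dict, float]] = []  # (coef by var, rhs)
        for allele in pop.alleles:
            p_h = pop.p[allele.name]
            for w in range(n_windows):
                const_score = 0.0
                coefs: dict[int, float] = {}
                for j in range(e_n):
                    pos = w + j
                    if pos in mut_set:
                        for a in M[pos]:
                            xi = self.x_index[(pos, a)]
                            coefs[xi] = coefs.get(xi, 0.0) + allele.phi[j, _aa20_index(a)]
                    else:
                        const_score += allele.phi[j, _aa20_index(prob.wild_type[pos])]
                if (allele.name, w) in self.y_index:
                    yi = self.y_index[(allele.name, w)]
                    c1[yi] = p_h
                    # y >= sum coefs * x + const_score - tau
                    row = dict(coefs)
                    row[yi] = row.get(yi, 0.0) - 1.0
                    hinge_rows.append((row, allele.tau - const_score))
                else:
                    const1 += p_h * max(0.0, const_score - allele.tau)
        self.c1 = c1
        self.const1 = const1

        # ---- constraints
        eq_rows: list[dict[int, float]] = []
        eq_rhs: list[float] = []
        ub_rows: list[tuple[dict[int, float], float]] = list(hinge_rows)

        for i in mutable:  # C1
            eq_rows.append({self.x_index[(i, a)]: 1.0 for a in M[i]})
            eq_rhs.append(1.0)

        for ii, i in enumerate(mutable):  # C2 / C3 (or their relaxation)
            for j in mutable[ii + 1:]:
                if not self.relax_linking:
                    for a in M[i]:
                        row = {self.w_index[(i, j, a, b)]: 1.0 for b in M[j]}
                        row[self.x_index[(i, a)]] = -1.0
                        eq_rows.append(row)
                        eq_rhs.append(0.0)
                    for b in M[j]:
                        row = {self.w_index[(i, j, a, b)]: 1.0 for a in M[i]}
                        row[self.x_index[(j, b)]] = -1.0
                        eq_rows.append(row)
                        eq_rhs.append(0.0)
                else:
                    for a in M[i]:
                        for b in M[j]:
                            widx = self.w_index[(i, j, a, b)]
                            if c2[widx] > 0:
                                # minimizing z2 pushes w down: force w >= x_i + x_j - 1
                                ub_rows.append(({widx: -1.0,
                                                 self.x_index[(i, a)]: 1.0,
                                                 self.x_index[(j, b)]: 1.0}, 1.0))
                            elif c2[widx] < 0:
                                # pushed up: cap by both incident x
                                ub_rows.append(({widx: 1.0, self.x_index[(i, a)]: -1.0}, 0.0))
                                ub_rows.append(({widx: 1.0, self.x_index[(j, b)]: -1.0}, 0.0))

        if mutable:  # C4: at most k deviations from the wild type
            row = {}
            for i in mutable:
                if (i, prob.wild_type[i]) in self.x_index:
                    row[self.x_index[(i, prob.wild_type[i])]] = -1.0
            ub_rows.append((row, float(prob.k) - len(mutable)))

        self.A_eq, self.b_eq = _rows_to_sparse(eq_rows, eq_rhs, var)
        A, b = zip(*ub_rows) if ub_rows else ([], [])
        self.A_ub, self.b_ub = _rows_to_sparse(list(A), list(b), var)
        self.stats = {"n_x": len(self.x_index), "n_w": len(self.w_index),
                      "n_y": len(self.y_index), "milp_solves": 0}

    # -- solving ----------------------------------------------------------

    def solve_single(self, objective: str,
                     z1_max: float = np.inf, z1_min: float = -np.inf,
                     z2_max: float = np.inf, z2_min: float = -np.inf,
                     extra_bound: tuple[str, float] | None = None) -> SolutionPoint:
        """Proven-optimal single-objective solve inside an objective-space box.

        Upper bounds on both objectives are exact; the lower bound on z1 is
        enforced on the slack representation and is therefore a relaxation
        (harmless for the Pareto logic, which never relies on lower bounds
        to cut off nondominated points).
        """
        if objective not in {"z1", "z2"}:
            raise ValueError("objective must be 'z1' or 'z2'")
        if self.n_vars == 0:
            # fully pinned problem: the wild type is the only candidate
            pt = self._wild_type_point()
            z1, z2 = pt.z
            ok = (z1 <= z1_max + 1e-9 and z1 >= z1_min - 1e-9
                  and z2 <= z2_max + 1e-9 and z2 >= z2_min - 1e-9)
            if ok and extra_bound is not None:
                obj, val = extra_bound
                ok = (z1 if obj == "z1" else z2) <= val + 1e-9
            return pt if ok else SolutionPoint(z=pt.z, sequence=pt.sequence,
                                               mutations=[], status="infeasible")

        c = self.c1 if objective == "z1" else self.c2
        constraints = []
        if self.A_eq.shape[0]:
            constraints.append(LinearConstraint(self.A_eq, self.b_eq, self.b_eq))
        lo = np.full(self.b_ub.shape, -np.inf)
        if self.A_ub.shape[0]:
            constraints.append(LinearConstraint(self.A_ub, lo, self.b_ub))

        extra_rows, extra_lo, extra_hi = [], [], []

        def add(vec: np.ndarray, low: float, high: float) -> None:
            extra_rows.append(vec)
            extra_lo.append(low)
            extra_hi.append(high)

        if np.isfinite(z1_max) or np.isfinite(z1_min):
            add(self.c1, z1_min - self.const1 if np.isfinite(z1_min) else -np.inf,
                z1_max - self.const1 if np.isfinite(z1_max) else np.inf)
        if np.isfinite(z2_max) or np.isfinite(z2_min):
            add(self.c2, z2_min - self.const2 if np.isfinite(z2_min) else -np.inf,
                z2_max - self.const2 if np.isfinite(z2_max) else np.inf)
        if extra_bound is not None:
            obj, val = extra_bound
            vec = self.c1 if obj == "z1" else self.c2
            cst = self.const1 if obj == "z1" else self.const2
            add(vec, -np.inf, val - cst)
        if extra_rows:
            constraints.append(LinearConstraint(sp.csr_matrix(np.array(extra_rows)),
                                                np.array(extra_lo), np.array(extra_hi)))

        res = milp(c=c, constraints=constraints, integrality=self.integrality,
                   bounds=Bounds(self.lb, self.ub), options={"mip_rel_gap": 0.0})
        self.stats["milp_solves"] += 1
        if res.status == 2:  # infeasible
            return SolutionPoint(z=(np.nan, np.nan), sequence="", mutations=[],
                                 status="infeasible")
        if res.status != 0 or res.x is None:
            raise RuntimeError(f"MILP backend failure: status {res.status} "
                               f"({res.message})")
        return self.decode(res.x)

    # -- decoding ---------------------------------------------------------

    def decode(self, assignment: np.ndarray) -> SolutionPoint:
        """Decode a variable vector into a sequence and re-derive both
        objectives from the x assignment alone (slack and pairing values
        from the backend are never trusted); a mismatch against the plain
        sequence-level objective evaluation beyond 1e-6 raises."""
        prob = self.problem
        seq = list(prob.wild_type)
        for i in self.mutable:
            chosen = [a for a in prob.mutation_sets.M[i]
                      if assignment[self.x_index[(i, a)]] > 0.5]
            ones = sum(1 for a in prob.mutation_sets.M[i]
                       if abs(assignment[self.x_index[(i, a)]] - 1) < 1e-4)
            if len(chosen) != 1 or ones != 1:
                raise ValueError(f"inconsistent assignment at position {i + 1} "
                                 f"(C1 violated)")
            seq[i] = chosen[0]
        sequence = "".join(seq)

        z1_ilp = self.const1
        pop = prob.population
        if pop.alleles:
            e_n = pop.e_n
            for allele in pop.alleles:
                for w in {wi for (an, wi) in self.y_index if an == allele.name}:
                    score = sum(allele.phi[j, _aa20_index(sequence[w + j])]
                                for j in range(e_n))
                    z1_ilp += pop.p[allele.name] * max(0.0, score - allele.tau)
        x_w = np.zeros(self.n_vars)
        for i in self.mutable:
            x_w[self.x_index[(i, sequence[i])]] = 1.0
        for (i, j, a, b), idx in self.w_index.items():
            if sequence[i] == a and sequence[j] == b:
                x_w[idx] = 1.0
        z2_ilp = float(self.c2 @ x_w) + self.const2

        z1_ref = immunogenicity_score(sequence, pop)
        z2_ref = -statistical_energy(prob.potts, sequence)
        if abs(z1_ilp - z1_ref) > 1e-6 or abs(z2_ilp - z2_ref) > 1e-6:
            raise ValueError(
                f"objective mismatch: ILP ({z1_ilp}, {z2_ilp}) vs "
                f"sequence-level ({z1_ref}, {z2_ref})")
        mutations = [(prob.offset + i, prob.wild_type[i], sequence[i])
                     for i in range(prob.n) if sequence[i] != prob.wild_type[i]]
        return SolutionPoint(z=(z1_ref, z2_ref), sequence=sequence,
                             mutations=mutations, status="optimal")

    def _wild_type_point(self) -> SolutionPoint:
        prob = self.problem
        z1 = immunogenicity_score(prob.wild_type, prob.population)
        z2 = -statistical_energy(prob.potts, prob.wild_type)
        return SolutionPoint(z=(z1, z2), sequence=prob.wild_type,
                             mutations=[], status="optimal")


def build_instance(problem: DesignProblem, relax_linking: bool = False) -> IlpInstance:
    """Assemble the MILP for a design problem."""
    return IlpInstance(problem=problem, relax_linking=relax_linking)


def _aa20_index(a: str) -> int:
    from .alphabet import AA20
    return AA20.index(a)


def _rows_to_sparse(rows: list[dict[int, float]], rhs: list[float],
                    n_vars: int) -> tuple[sp.csr_matrix, np.ndarray]:
    data, ri, ci = [], [], []
    for r, row in enumerate(rows):
        for c, v in row.items():
            ri.append(r)
            ci.append(c)
            data.append(v)
    A = sp.csr_matrix((data, (ri, ci)), shape=(len(rows), n_vars))
    return A, np.asarray(rhs, dtype=float)
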