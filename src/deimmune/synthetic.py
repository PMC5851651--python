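"""Synthetic generators: random allele PSSMs, random Potts models, Gibbs
sampling of alignments, and fully wired toy design problems.

Every generator is a pure function of its seed (numpy PCG64 via
``default_rng``), so fixtures are reproducible across runs and platforms to
the extent the RNG algorithm guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA20
from .epitopes import AlleleModel, Population, binding_threshold
from .ilp import DesignProblem
from .msa import Alignment, MutationSets
from .potts import PottsModel


@dataclass
class ToySpec:
    """Shape of a brute-force-enumerable toy design problem."""

    n: int = 8
    q: int = 4  # alphabet size (first q residues of AA20, no gap)
    m_max: int = 3  # largest |M_i|
    n_alleles: int = 2
    e_n: int = 3
    k: int = 2
    seed: int = 0
    percentile: float = 75.0
    total_frequency: float = 0.7
    limit: int = 20_000  # max brute-force candidates

    def __post_init__(self) -> None:
        if not (2 <= self.q <= 20):
            raise ValueError("q must lie in [2, 20]")
        if self.e_n > self.n:
            raise ValueError("binding core longer than the sequence")


def random_pssm(e_n: int, seed: int, planted_binder: str | None = None,
                boost: float = 3.0, name: str | None = None) -> AlleleModel:
    """PSSM with i.i.d. standard-normal cells; optionally boost the cells of
    ``planted_binder`` so that peptide is the unique argmax window."""
    if e_n < 1:
        raise ValueError("e_n must be >= 1")
    rng = np.random.default_rng(seed)
    phi = rng.standard_normal((e_n, len(AA20)))
    if planted_binder is not None:
        if len(planted_binder) != e_n:
            raise ValueError("planted binder length must equal e_n")
        for j, c in enumerate(planted_binder):
            phi[j, AA20.index(c)] += boost
    return AlleleModel(name=name or f"SYN-{seed:04d}", phi=phi)


def random_potts(L: int, q: int, coupling_density: float = 0.25,
                 scale: float = 1.0, seed: int = 0,
                 field_scale: float = 1.0) -> PottsModel:
    """Potts model with Gaussian fields and sparse symmetric couplings.

    Each of the L(L-1)/2 pairs carries a dense q x q Gaussian coupling block
    with probability ``coupling_density``; ``scale`` is the entry standard
    deviation. The alphabet is the first q standard residues (no gap state).
    """
    if L < 2 or q < 2:
        raise ValueError("need L >= 2 and q >= 2")
    rng = np.random.default_rng(seed)
    h = field_scale * rng.standard_normal((L, q))
    J = np.zeros((L, L, q, q))
    for i in range(L):
        for j in range(i + 1, L):
            if rng.random() < coupling_density:
                block = scale * rng.standard_normal((q, q))
                J[i, j] = block
                J[j, i] = block.T
    return PottsModel(h=h, J=J, alphabet=AA20[:q],
                      meta={"seed": seed, "coupling_density": coupling_density,
                            "scale": scale})


def gibbs_sample(model: PottsModel, n_seq: int, burn_in: int = 200,
                 thin: int = 5, seed: int = 0,
                 max_chains: int = 2000) -> Alignment:
    """Sample sequences by single-site Gibbs sweeps.

    Independent chains run in parallel (vectorized over chains); each chain
    contributes samples spaced ``thin`` full sweeps apart after ``burn_in``
    sweeps. With zero couplings the empirical single-site marginals converge
    to softmax(h_i).
    """
    if n_seq < 1:
        raise ValueError("n_seq must be >= 1")
    rng = np.random.default_rng(seed)
    L, q = model.L, model.q
    chains = min(n_seq, max_chains)
    per_chain = -(-n_seq // chains)  # ceil
    S = rng.integers(0, q, size=(chains, L))
    samples = []

    def sweep() -> None:
        for i in range(L):
            logits = np.tile(model.h[i], (chains, 1))
            for j in range(L):
                if j != i:
                    logits += model.J[i, j][:, S[:, j]].T
            # Gumbel-max categorical draw, vectorized over chains
            g = rng.gumbel(size=(chains, q))
            S[:, i] = np.argmax(logits + g, axis=1)

    for _ in range(burn_in):
        sweep()
    for t in range(per_chain):
        if t > 0:
            for _ in range(thin):
                sweep()
        samples.append(S.copy())
    X = np.concatenate(samples, axis=0)[:n_seq]
    chars = np.array(list(model.alphabet))
    matrix = chars[X]
    ids = [f"sample_{i}" for i in range(n_seq)]
    return Alignment(ids=ids, matrix=matrix,
                     focus_columns=np.arange(L), target_id=ids[0],
                     weights=np.ones(n_seq))


def make_toy_problem(spec: ToySpec) -> DesignProblem:
    """Wire random PSSMs, a random Potts model, a random wild type and
    protein-context thresholds into a solvable, enumerable design problem."""
    rng = np.random.default_rng(spec.seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    alphabet = AA20[:spec.q]

    potts = random_potts(spec.n, spec.q, coupling_density=0.5, scale=0.6,
                         seed=int(sub[0]))
    wt = "".join(alphabet[i] for i in rng.integers(0, spec.q, size=spec.n))

    M = []
    for i in range(spec.n):
        size = int(rng.integers(1, spec.m_max + 1))
        opts = {wt[i]}
        pool = [a for a in alphabet if a != wt[i]]
        extra = rng.choice(len(pool), size=min(size - 1, len(pool)), replace=False)
        opts.update(pool[t] for t in extra)
        M.append(sorted(opts, key=AA20.index))
    mutable = frozenset(i + 1 for i in range(spec.n) if len(M[i]) > 1)
    msets = MutationSets(M=M, wild_type=wt, zeta=0.0, mutable_positions=mutable)

    alleles = []
    p = {}
    raw = rng.uniform(0.5, 1.0, size=spec.n_alleles)
    raw = spec.total_frequency * raw / raw.sum()
    for a in range(spec.n_alleles):
        allele = random_pssm(spec.e_n, seed=int(sub[1]) + a,
                             name=f"TOY-{spec.seed}-{a}")
        binding_threshold(allele, percentile=spec.percentile,
                          background="protein", context=wt)
        alleles.append(allele)
        p[allele.name] = float(raw[a])
    pop = Population(alleles=alleles, p=p)

    problem = DesignProblem(wild_type=wt, mutation_sets=msets, k=spec.k,
                            population=pop, potts=potts)
    _check_enumerable(problem, spec.limit)
    return problem


def _check_enumerable(problem: DesignProblem, limit: int) -> None:
    from itertools import combinations

    M = problem.mutation_sets.M
    mutable = [i for i in range(problem.n) if len(M[i]) > 1]
    total = 0
    for r in range(min(problem.k, len(mutable)) + 1):
        for combo in combinations(mutable, r):
            c = 1
            for i in combo:
                c *= len(M[i]) - 1
            total += c
    if total > limit:
        raise ValueError(f"toy spec yields {total} candidates, above {limit}")
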