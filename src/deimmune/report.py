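"""Design reporting: mutation strings, percent changes against the wild
type, epitope tables and mutational-landscape percentiles.

Sign conventions (also written into every TSV header): dI = I(design) -
I(wild type), negative when immunogenicity was reduced; dE = E(wild type) -
E(design) in statistical-energy units, positive when predicted fitness was
lost. Both match the direction in which a de-immunization trade-off is
usually read: good designs have negative dI and small positive dE.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy.stats import percentileofscore

from .alphabet import GAP
from .epitopes import epitope_count
from .ilp import DesignProblem, SolutionPoint
from .pareto import ParetoFront
from .potts import PottsModel, mutation_effect

_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

_SIGN_HEADER = ("# dI = I(design) - I(wt); dE = E(wt) - E(design), "
                "positive dE = predicted fitness loss")


def mutation_string(mutations: list[tuple[int, str, str]]) -> str:
    """'V2333E'-style comma-joined mutation list in protein numbering."""
    return ",".join(f"{wt}{pos}{new}" for pos, wt, new in mutations)


def parse_mutation_string(s: str) -> list[tuple[int, str, str]]:
    if not s:
        return []
    out = []
    for token in s.split(","):
        m = _MUT_RE.match(token.strip())
        if m is None:
            raise ValueError(f"unparseable mutation {token!r}")
        out.append((int(m.group(2)), m.group(1), m.group(3)))
    return out


def percent_change(front: ParetoFront, wild_type_point: SolutionPoint
                   ) -> pd.DataFrame:
    """Per-design percent change of both objectives vs the wild type:
    100 * (z - z_wt) / |z_wt|. If a wild-type objective is zero the absolute
    delta is reported instead and flagged in the ``*_absolute`` column."""
    rows = []
    for p in front.points:
        row = {}
        for name, idx in (("immunogenicity", 0), ("neg_energy", 1)):
            z_wt = wild_type_point.z[idx]
            delta = p.z[idx] - z_wt
            if z_wt == 0:
                row[f"{name}_change"] = delta
                row[f"{name}_absolute"] = True
            else:
                row[f"{name}_change"] = 100.0 * delta / abs(z_wt)
                row[f"{name}_absolute"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def single_mutant_effects(model: PottsModel, wild_type: str) -> np.ndarray:
    """dE = E(mutant) - E(wt) for every single substitution, vectorized.

    Returns a flat array over (position, residue != wt, residue != gap).
    """
    wt = model.encode(wild_type)
    L = model.L
    out = []
    gap_states = [a for a, c in enumerate(model.alphabet) if c == GAP]
    for i in range(L):
        base = model.h[i, wt[i]]
        others = np.setdiff1d(np.arange(L), [i])
        pair_wt = model.J[i, others, wt[i], wt[others]].sum()
        for a in range(model.q):
            if a == wt[i] or a in gap_states:
                continue
            d = model.h[i, a] - base
            d += model.J[i, others, a, wt[others]].sum() - pair_wt
            out.append(d)
    return np.array(out)


def landscape_percentile(model: PottsModel, wild_type: str, k_max: int,
                         design_effect: float, sample_budget: int = 10_000,
                         seed: int = 0, exhaustive: bool = False
                         ) -> dict[int, float]:
    """Percentile of a design's fitness change within the mutational
    landscape, per mutation load 1..k_max.

    Singles are enumerated exhaustively; higher loads are sampled with
    ``sample_budget`` draws each (or enumerated when ``exhaustive`` on small
    models). Percentile is the weak-ordering fraction P(dE_landscape <=
    design_effect) * 100, so fitter-than-everything designs sit at 100.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if sample_budget < 100:
        raise ValueError("sample budget below 100 is not meaningful")
    rng = np.random.default_rng(seed)
    wt = model.encode(wild_type)
    non_gap = [a for a, c in enumerate(model.alphabet) if c != GAP]
    result: dict[int, float] = {}
    singles = single_mutant_effects(model, wild_type)
    result[1] = float(percentileofscore(singles, design_effect, kind="weak"))
    for r in range(2, k_max + 1):
        if exhaustive:
            from itertools import combinations, product
            effects = []
            for combo in combinations(range(model.L), r):
                pools = [[a for a in non_gap if a != wt[i]] for i in combo]
                for choice in product(*pools):
                    muts = {i + 1: model.alphabet[a] for i, a in zip(combo, choice)}
                    effects.append(mutation_effect(model, wild_type, muts))
            effects = np.array(effects)
        else:
            effects = np.empty(sample_budget)
            for t in range(sample_budget):
                pos = rng.choice(model.L, size=r, replace=False)
                muts = {}
                for i in pos:
                    choices = [a for a in non_gap if a != wt[i]]
                    muts[int(i) + 1] = model.alphabet[int(rng.choice(choices))]
                effects[t] = mutation_effect(model, wild_type, muts)
        result[r] = float(percentileofscore(effects, design_effect, kind="weak"))
    return result


def design_report(front: ParetoFront, problem: DesignProblem,
                  wild_type_point: SolutionPoint,
                  landscape: bool = False, sample_budget: int = 10_000,
                  seed: int = 0) -> pd.DataFrame:
    """Tabular summary of a front: one row per design plus the wild type.

    Columns: ID, Mutation, Epitopes, dI, dE (conventions in the module
    docstring) and, when ``landscape`` is on, the percentile of the design's
    fitness change within its own mutation-load landscape."""
    rows = [{"ID": "wt", "Mutation": "", "Epitopes":
             epitope_count(problem.wild_type, problem.population),
             "dI": 0.0, "dE": 0.0}]
    for idx, p in enumerate(front.points):
        if not p.mutations:
            continue
        row = {"ID": str(idx), "Mutation": mutation_string(p.mutations),
               "Epitopes": epitope_count(p.sequence, problem.population),
               "dI": p.z[0] - wild_type_point.z[0],
               "dE": p.z[1] - wild_type_point.z[1]}
        if landscape:
            effect = -(p.z[1] - wild_type_point.z[1])  # E(mut) - E(wt)
            k = len(p.mutations)
            pct = landscape_percentile(problem.potts, problem.wild_type,
                                       max(k, 1), effect,
                                       sample_budget=sample_budget, seed=seed)
            row["LandscapePct"] = pct[k]
        rows.append(row)
    return pd.DataFrame(rows)


def write_report_tsv(report: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_SIGN_HEADER + "\n")
        report.to_csv(fh, sep="\t", index=False)


def write_front_fasta(front: ParetoFront, path, prefix: str = "design") -> None:
    """FASTA of designed sequences, mutation strings in the headers."""
    with open(path, "w") as fh:
        for idx, p in enumerate(front.points):
            tag = mutation_string(p.mutations) or "wild-type"
            fh.write(f">{prefix}_{idx} {tag}\n{p.sequence}\n")
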