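"""HLA class II epitope scoring and the population immunogenicity objective.

Each allele is a TEPITOPE-style position-specific scoring matrix over a
9-mer binding core; a peptide's score is the sum of matrix cells along the
core. Windows scoring above the allele's binding threshold tau are epitope
calls, and the immunogenicity of a sequence is the allele-frequency-weighted
sum of above-threshold margins (a hinge loss), so that weak binders drop
out and strong binders count in proportion to their excess over tau.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import AA20


@dataclass
class AlleleModel:
    """One HLA allele: PSSM ``phi`` (e_n x 20, columns ordered as AA20),
    core length ``e_n`` and binding threshold ``tau`` (None until set)."""

    name: str
    phi: np.ndarray
    tau: float | None = None
    normalized: bool = False
    norm_params: tuple[float, float] | None = None  # (mean, sd) applied

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2 or self.phi.shape[1] != len(AA20):
            raise ValueError("PSSM must be (e_n, 20) with AA20 column order")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("non-finite PSSM cells")

    @property
    def e_n(self) -> int:
        return self.phi.shape[0]


@dataclass
class Population:
    """HLA alleles with their frequencies in the target population."""

    alleles: list[AlleleModel]
    p: dict[str, float]

    def __post_init__(self) -> None:
        freqs = np.array([self.p[a.name] for a in self.alleles])
        if np.any(freqs < 0):
            raise ValueError("negative allele frequency")
        if freqs.sum() > 1 + 1e-9:
            raise ValueError("allele frequencies sum above 1")
        e_ns = {a.e_n for a in self.alleles}
        if len(e_ns) > 1:
            raise ValueError("alleles disagree on core length")

    @property
    def e_n(self) -> int:
        return self.alleles[0].e_n

    def frequency(self, name: str) -> float:
        return self.p[name]


@dataclass
class EpitopeCall:
    start: int  # 1-based start of the core window, protein numbering
    allele: str
    score: float
    margin: float  # score - tau, > 0 for every call


_AA_INDEX = {c: i for i, c in enumerate(AA20)}


def write_pssm(model: AlleleModel, path) -> None:
    """Write the documented TSV: '# allele NAME' header, AA20 columns,
    one row per core position; full float precision."""
    lines = [f"# allele\t{model.name}", "pos\t" + "\t".join(AA20)]
    for j in range(model.e_n):
        lines.append(str(j) + "\t" + "\t".join(repr(float(v)) for v in model.phi[j]))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_pssm(path, e_n: int | None = None) -> AlleleModel:
    """Read a PSSM TSV written by :func:`write_pssm` (or hand-authored in
    the same layout). ``e_n`` optionally asserts the expected core length."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln.rstrip("\n") for ln in io.StringIO(text) if ln.strip()]
    if not lines or not lines[0].startswith("# allele"):
        raise ValueError("missing '# allele' header line")
    name = lines[0].split("\t", 1)[1].strip()
    header = lines[1].split("\t")
    if header[0] != "pos" or header[1:] != list(AA20):
        raise ValueError("column header must be 'pos' followed by the 20 residues")
    rows = []
    for ln in lines[2:]:
        parts = ln.split("\t")
        if len(parts) != len(AA20) + 1:
            raise ValueError(f"malformed row: {ln!r}")
        rows.append([float(v) for v in parts[1:]])
    phi = np.array(rows)
    if e_n is not None and phi.shape[0] != e_n:
        raise ValueError(f"core length {phi.shape[0]} != declared e_n {e_n}")
    return AlleleModel(name=name, phi=phi)


def znormalize(model: AlleleModel) -> AlleleModel:
    """Z-score the PSSM over its pooled cells; adjust tau consistently.

    A raw peptide score s maps to (s - e_n * mu) / sd, so transforming
    tau the same way preserves every score-threshold comparison.
    """
    if model.normalized:
        raise ValueError(f"allele {model.name} already normalized")
    mu = float(model.phi.mean())
    sd = float(model.phi.std())
    if sd == 0:
        raise ValueError(f"allele {model.name}: constant matrix, sd = 0")
    tau = None if model.tau is None else (model.tau - model.e_n * mu) / sd
    return replace(model, phi=(model.phi - mu) / sd, tau=tau,
                   normalized=True, norm_params=(mu, sd))


def peptide_score(model: AlleleModel, peptide: str) -> float:
    """Sum of PSSM cells along the binding core."""
    if len(peptide) != model.e_n:
        raise ValueError(f"peptide length {len(peptide)} != core length {model.e_n}")
    try:
        cols = [_AA_INDEX[c] for c in peptide]
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} not a standard residue") from None
    return float(model.phi[np.arange(model.e_n), cols].sum())


def window_scores(model: AlleleModel, seq: str) -> np.ndarray:
    """Scores of all e_n-wide windows of ``seq`` (length n - e_n + 1)."""
    n, e_n = len(seq), model.e_n
    if n < e_n:
        raise ValueError(f"sequence shorter than the binding core ({n} < {e_n})")
    try:
        idx = np.array([_AA_INDEX[c] for c in seq])
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} not a standard residue") from None
    cell = model.phi[np.arange(e_n)[None, :], np.lib.stride_tricks.sliding_window_view(idx, e_n)]
    return cell.sum(axis=1)


def binding_threshold(model: AlleleModel, percentile: float = 95.0,
                      background: str = "protein", context: str | None = None,
                      n_samples: int = 10000, seed: int = 0) -> float:
    """Set tau as a percentile of a background score distribution.

    ``protein`` mode uses the empirical distribution of all windows of the
    supplied context protein (the screening described for the target
    domain); ``uniform-random`` draws ``n_samples`` random cores, seeded.
    The threshold is stored on the model and returned.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    if background == "protein":
        if context is None:
            raise ValueError("protein background requires a context sequence")
        scores = window_scores(model, context)
    elif background == "uniform-random":
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, len(AA20), size=(n_samples, model.e_n))
        scores = model.phi[np.arange(model.e_n)[None, :], draws].sum(axis=1)
    else:
        raise ValueError(f"unknown background {background!r}")
    tau = float(np.percentile(scores, percentile))
    model.tau = tau
    return tau


def _require_thresholds(population: Population) -> None:
    missing = [a.name for a in population.alleles if a.tau is None]
    if missing:
        raise ValueError(f"alleles without binding threshold: {missing}")


def scan_epitopes(seq: str, population: Population, offset: int = 1) -> list[EpitopeCall]:
    """All (window, allele) pairs scoring strictly above the allele threshold.

    Window starts are reported in protein numbering (first residue of the
    sequence = ``offset``)."""
    _require_thresholds(population)
    calls: list[EpitopeCall] = []
    for allele in population.alleles:
        scores = window_scores(allele, seq)
        for w in np.nonzero(scores > allele.tau)[0]:
            calls.append(EpitopeCall(start=offset + int(w), allele=allele.name,
                                     score=float(scores[w]),
                                     margin=float(scores[w] - allele.tau)))
    calls.sort(key=lambda c: (c.start, c.allele))
    return calls


def immunogenicity_score(seq: str, population: Population) -> float:
    """Population immunogenicity: sum_h p_h sum_windows max(0, score - tau_h)."""
    if not population.alleles:
        return 0.0
    _require_thresholds(population)
    total = 0.0
    for allele in population.alleles:
        scores = window_scores(allele, seq)
        total += population.p[allele.name] * float(np.clip(scores - allele.tau, 0, None).sum())
    return total


def epitope_count(seq: str, population: Population) -> int:
    """Number of (window, allele) epitope calls; a core binding two alleles
    counts twice."""
    return len(scan_epitopes(seq, population))
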