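"""Evolutionary coupling scores from a Potts model.

Pair scores are Frobenius norms of the coupling blocks in zero-sum gauge
(gap state excluded), corrected with the average product correction (APC)
to remove sampling and phylogenetic background. Top couplings are called by
fitting a two-component Gaussian + lognormal mixture to the long-range
score distribution and thresholding the lognormal membership posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import lognorm, norm

from .alphabet import GAP
from .potts import PottsModel


@dataclass
class ECResult:
    fn: np.ndarray  # (L, L) Frobenius-norm scores, symmetric, zero diag
    apc: np.ndarray  # (L, L) APC-corrected scores
    enrichment: np.ndarray | None = None
    top_set: list[tuple[int, int]] | None = None  # 1-based (i, j), i < j
    mixture_params: dict | None = None
    meta: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.fn.shape[0]


def _zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    row = block.mean(axis=1, keepdims=True)
    col = block.mean(axis=0, keepdims=True)
    return block - row - col + block.mean()


def ec_scores(model: PottsModel) -> ECResult:
    """Frobenius-norm coupling scores with APC.

    Each J_ij block is moved to zero-sum gauge over the residue states (the
    gap state, if present in the alphabet, is dropped first), then
    fn(i,j) = ||J_ij||_F and apc(i,j) = fn(i,j) - fn_i * fn_j / fn_mean with
    row means taken over partners j != i.
    """
    L = model.L
    states = [a for a, c in enumerate(model.alphabet) if c != GAP]
    fn = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            block = model.J[i, j][np.ix_(states, states)]
            g = _zero_sum_gauge(block)
            fn[i, j] = fn[j, i] = float(np.sqrt((g ** 2).sum()))
    apc = apply_apc(fn)
    return ECResult(fn=fn, apc=apc)


def apply_apc(fn: np.ndarray) -> np.ndarray:
    """Average product correction of a symmetric score matrix.

    apc(i,j) = fn(i,j) - mean_i(fn) * mean_j(fn) / mean(fn), means over
    off-diagonal entries; the diagonal stays zero.
    """
    L = fn.shape[0]
    if L < 2:
        return np.zeros_like(fn)
    off = ~np.eye(L, dtype=bool)
    row_mean = fn.sum(axis=1) / (L - 1)
    all_mean = fn[off].mean()
    if all_mean == 0:
        return np.zeros_like(fn)
    apc = fn - np.outer(row_mean, row_mean) / all_mean
    apc[np.eye(L, dtype=bool)] = 0.0
    return apc


def ec_enrichment(ec: ECResult, normalize: bool = True,
                  pairs: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Cumulative coupling score per position.

    enrichment(i) = sum_j apc(i, j), optionally restricted to a pair subset
    (e.g. the top-EC set) and normalized by the mean over positions.
    """
    if pairs is None:
        enr = ec.apc.sum(axis=1)
    else:
        enr = np.zeros(ec.L)
        for i, j in pairs:
            enr[i - 1] += ec.apc[i - 1, j - 1]
            enr[j - 1] += ec.apc[i - 1, j - 1]
    if normalize:
        m = enr.mean()
        if m != 0:
            enr = enr / m
    ec.enrichment = enr
    return enr


def fit_gaussian_lognormal(x: np.ndarray, max_iter: int = 1000,
                           tol: float = 1e-10) -> dict:
    """EM fit of pi * LogNormal + (1 - pi) * Normal to scores ``x``.

    The lognormal carries the signal tail (support x > 0), the Gaussian the
    background. Initialization is moment-based with the tail component
    seeded from scores above the 90th percentile. Returns the parameter
    dict; ``degenerate`` is set when a component collapses, in which case
    callers should fall back to a rank cutoff.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    t0 = np.percentile(x, 90)
    tail = x[(x > t0) & (x > 0)]
    if tail.size < 3 or np.all(x <= 0):
        return {"degenerate": True}
    rest = x[x <= t0]
    pi = tail.size / n
    mu_g, sd_g = float(rest.mean()), float(max(rest.std(), 1e-6))
    mu_l, sd_l = float(np.log(tail).mean()), float(max(np.log(tail).std(), 1e-3))

    resp = np.zeros(n)
    ll_old = -np.inf
    for _ in range(max_iter):
        pos = x > 0
        dens_l = np.zeros(n)
        dens_l[pos] = lognorm.pdf(x[pos], s=sd_l, scale=np.exp(mu_l))
        dens_g = norm.pdf(x, loc=mu_g, scale=sd_g)
        num = pi * dens_l
        den = num + (1 - pi) * dens_g
        ok = den > 0
        resp[:] = 0.0
        resp[ok] = num[ok] / den[ok]
        ll = float(np.log(den[ok]).sum())

        pi = float(resp.mean())
        w_g = 1.0 - resp
        if w_g.sum() < 1e-9 or resp[pos].sum() < 1e-9 or not (1e-9 < pi < 1 - 1e-9):
            return {"degenerate": True}
        mu_g = float((w_g * x).sum() / w_g.sum())
        sd_g = float(max(np.sqrt((w_g * (x - mu_g) ** 2).sum() / w_g.sum()), 1e-6))
        lx = np.log(x[pos])
        rp = resp[pos]
        mu_l = float((rp * lx).sum() / rp.sum())
        sd_l = float(max(np.sqrt((rp * (lx - mu_l) ** 2).sum() / rp.sum()), 1e-3))
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            break
        ll_old = ll
    return {"degenerate": False, "pi_lognormal": pi, "mu_gauss": mu_g,
            "sd_gauss": sd_g, "mu_log": mu_l, "sd_log": sd_l,
            "loglik": ll}


def lognormal_posterior(x: np.ndarray, params: dict) -> np.ndarray:
    """Posterior probability that each score belongs to the lognormal tail."""
    x = np.asarray(x, dtype=float)
    post = np.zeros(x.size)
    pos = x > 0
    dens_l = np.zeros(x.size)
    dens_l[pos] = lognorm.pdf(x[pos], s=params["sd_log"], scale=np.exp(params["mu_log"]))
    dens_g = norm.pdf(x, loc=params["mu_gauss"], scale=params["sd_gauss"])
    num = params["pi_lognormal"] * dens_l
    den = num + (1 - params["pi_lognormal"]) * dens_g
    ok = den > 0
    post[ok] = num[ok] / den[ok]
    return post


def top_ecs(ec: ECResult, min_separation: int = 5, prob: float = 0.9,
            fallback_fraction: float = 0.01) -> list[tuple[int, int]]:
    """Call significant long-range couplings.

    Fits the Gaussian + lognormal mixture to all APC scores of pairs with
    |i - j| >= min_separation and returns the pairs (1-based, i < j) whose
    lognormal membership posterior is >= ``prob``. On EM degeneracy the top
    ``fallback_fraction`` of pairs by score is returned and flagged in
    ``ec.meta['fallback']``.
    """
    L = ec.L
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L)
             if j - i >= min_separation]
    if len(pairs) < 50:
        raise ValueError(f"only {len(pairs)} long-range pairs; need >= 50")
    scores = np.array([ec.apc[i, j] for i, j in pairs])
    params = fit_gaussian_lognormal(scores)
    if params.get("degenerate", False):
        k = max(1, int(round(fallback_fraction * len(pairs))))
        order = np.argsort(scores)[::-1][:k]
        top = sorted((pairs[t][0] + 1, pairs[t][1] + 1) for t in order)
        ec.top_set = top
        ec.mixture_params = params
        ec.meta["fallback"] = True
        return top
    post = lognormal_posterior(scores, params)
    top = sorted((pairs[t][0] + 1, pairs[t][1] + 1)
                 for t in np.nonzero(post >= prob)[0])
    ec.top_set = top
    ec.mixture_params = params
    ec.meta["fallback"] = False
    return top
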