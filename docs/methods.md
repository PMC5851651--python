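# Methods

This note documents the models, numerical choices and limitations of
`deimmune`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem statement

Given a wild-type sequence W of length n, per-position candidate sets M_i,
a mutation budget k, a population {(h, p_h)} of HLA class II alleles with
scoring matrices Φ and thresholds τ_h, and a family Potts model (h_i, J_ij),
find all mutants S′ (S′[i] ∈ M_i, Hamming(S′, W) ≤ k) that are Pareto-optimal
for

    minimize ( I(S′),  −E(S′) )

with I the hinge-thresholded, frequency-weighted window score and E the
Potts statistical energy. Both objectives take finitely many values over
the (finite) design space, so the front is finite and can be computed
exactly.

## Alignment preparation

- **Focus columns.** The family alignment is reduced to the columns in
  which the target record carries a residue (A2M match states for A2M
  input). Position i (1-based) maps to protein residue `offset + i − 1`.
- **Gap filtering.** Sequences with ≥ 70% gaps and columns with > 50% gaps
  are removed (the asymmetry of ≥ vs > is deliberate and matches the stated
  rules). Removal is iterated to a fixed point so both bounds hold
  simultaneously on the result; this also makes the filter idempotent. The
  target record is never removed.
- **Reweighting.** Sequence weight = 1 / (number of sequences at identity
  ≥ θ, self included), Meff = Σ weights, default θ = 0.9. Identity is
  computed over focus columns with any gap position counting as a mismatch
  (only modeled positions should drive weights); the self-count is always
  included so weights stay in (0, 1].
- **Substitution sets.** M_i = {a : f_i(a) ≥ ζ} ∪ {W[i]} at mutable
  positions, with gap frequency dropped and the residue frequencies
  renormalized first — designs cannot contain gaps. At ζ = 0 only residues
  actually observed qualify. Immutable positions are pinned to W[i].

## Potts model

- **Energy convention.** E(X) = Σ_{i<j} J_ij(X_i,X_j) + Σ_i h_i(X_i) is the
  log-unnormalized probability (P ∝ e^E): higher E = fitter. The design
  objective minimizes −E. The partition function is never computed; all
  downstream quantities are energies or energy differences, which are
  invariant under gauge shifts h_i(a) → h_i(a) + c_i (verified numerically
  in the tests).
- **Inference.** Weighted pseudo-likelihood maximization: the sum over
  sites of conditional negative log-likelihoods, minimized jointly with
  L-BFGS, so the coupling estimates are symmetric by construction. The gap
  is a 21st alphabet state for family alignments; synthetic models may use
  smaller gap-free alphabets.
- **Regularization.** λ_h = 0.01 and λ_J = 0.1·Meff by default. λ_J was
  calibrated on synthetic recovery experiments (known L=10, q=4 ground
  truth, 5,000 Gibbs samples): much weaker penalties leave sampling-noise
  couplings of ~0.1–0.2 on data with no true couplings (the penalty must
  compete with the pseudolikelihood curvature, which grows with Meff), while
  much stronger ones shrink true couplings enough to degrade held-out energy
  correlation below 0.9. The maximum spurious coupling is an extreme-value
  statistic over L(L−1)/2·q² parameters; at the default it concentrates
  around 0.03–0.08 across sampling seeds. Both λ are exposed.
- **Convergence.** L-BFGS with gradient tolerance 1e-5, max 500 iterations;
  non-convergence is flagged in `meta["converged"]` with the final gradient
  norm, and the parameters are still returned.

## Evolutionary couplings

- Pair score: Frobenius norm of the J_ij block in zero-sum gauge, gap state
  excluded (standard practice; the gap row/column carries alignment
  artifacts, not structural signal).
- APC: apc(i,j) = fn(i,j) − fn_i·fn_j / fn_mean with row means over
  partners j ≠ i and the grand mean over off-diagonal entries.
- Enrichment: row sums of apc, optionally restricted to a pair subset
  (e.g. the top-EC set) and normalized by the positional mean. Both the
  all-pairs and top-N modes are provided because cumulative scores are
  reported both ways in practice.
- Top-EC calling: two-component mixture — Gaussian background plus
  lognormal tail (density zero for scores ≤ 0) — fitted by EM to all pair
  scores with |i−j| ≥ 5 ("long-range"; the separation is configurable).
  Initialization is moment-based with the tail seeded from scores above the
  90th percentile, which makes the fit deterministic. Pairs with posterior
  lognormal membership ≥ 0.9 are called. If the EM degenerates (no positive
  tail, component collapse), the top 1% of pairs by score is returned and
  the result is flagged `fallback` — rank cutoffs are the field's usual
  refuge when the score distribution has no separable tail.

## Immunogenicity

- Peptide score = Σ_j Φ(h, peptide[j], j) over the e_n-long core (default
  9). Matrices may be z-normalized per allele (pooled cell mean/sd); the
  threshold transforms as τ → (τ − e_n·μ)/σ, which preserves every
  score-vs-threshold comparison exactly (asserted to 1e-9).
- Thresholds: a percentile (default 95) of either the empirical window-score
  distribution of a context protein — reproducing a whole-domain screening —
  or of seeded uniform-random peptides. The choice is recorded on the model.
- Epitope calls are (window, allele) pairs with score strictly above τ_h; a
  core binding two alleles counts twice, matching the double sum in I.
- I(S′) sums over all n − e_n + 1 full windows of the domain, not only the
  design region: mutations change flanking epitopes too.
- Φ is allowed to be real-valued (z-normalization produces negative cells);
  the hinge handles the sign.

## ILP encoding

- Binary x_{i,a} only for mutable positions; immutable positions are folded
  into constants (fields, immutable-pair couplings) and into linear
  coefficients (mutable–immutable couplings), so reported z2 = −E is always
  the *full-sequence* energy, comparable across designs.
- Pairing variables w_{i,j,a,b} are continuous in [0,1]: with the exact
  linking equalities (C2/C3) and binary x they are forced to x_{i,a}·x_{j,b}
  at any feasible point. C1 selects one residue per position; C4 bounds the
  Hamming distance via Σ_i (1 − x_{i,W[i]}) ≤ k.
- Hinge linearization: one slack y_{h,win} ≥ (window score) − τ_h, y ≥ 0 per
  allele/window touching a mutable position; windows touching none
  contribute constants. The linearization is exact when z1 is minimized or
  upper-bounded; slacks are free to inflate under lower bounds, so decoded
  solutions always re-derive both objectives from x alone and raise on any
  mismatch beyond 1e-6. This check certifies the hinge rows and the
  w-linking constraints on every solve.
- A positive/negative splitting of the linking constraints (inequalities
  only where the objective sign pushes w the wrong way) is available behind
  `relax_linking`; it reproduces the exact optima on the test problems but
  is only directionally safe, so the Pareto solver always uses the exact
  equalities.
- Backend: HiGHS through `scipy.optimize.milp`, `mip_rel_gap = 0` (proven
  optimality, which the rectangle logic requires).

## Pareto search

- **lexmin**: minimize the primary objective in the box, then the secondary
  subject to primary ≤ optimum + δ. Stage 2 is feasible whenever stage 1
  is; this is asserted.
- **Boundaries**: z_T = lexmin(z1, z2), z_B = lexmin(z2, z1), independent
  solves.
- **Phase 1**: the z1 range [z1_T, z1_B] is cut at m even boundaries τ_i;
  each slice solves lexmin with z2 primary under the exact constraint
  z1 ≤ τ_i, yielding the nondominated point with the largest z1 not
  exceeding τ_i. This departs from slicing with *lower* bounds on z1
  because a z1 lower bound cannot be expressed exactly through hinge slacks
  (inflated slacks would admit dominated interlopers); the upper-bound form
  produces only globally nondominated points, keeps the even spread, always
  recovers z_B, and guarantees phase-1 ⊆ final front. Slice boundaries are
  effectively half-open: duplicates across slices are merged at δ.
- **Phase 2**: adjacent points spawn rectangles. Each rectangle is split at
  the z2 midline; the bottom half is searched z1-first, and the top half —
  restricted to z1 ≤ (new point's z1) − ε — z2-first. Rediscovering a corner
  proves its half empty; new points spawn child rectangles. z1 lower bounds
  are dropped everywhere: any feasible point below a corner's z1 with z2
  under the midline would dominate that corner, contradicting its
  nondominance, so the bounds are redundant as long as corners are
  nondominated (which lexmin maintains).
- **Parallelism**: slices and rectangles are independent work items
  (threads; HiGHS instances are per-call). Results merge through a
  dominance filter, so the front is invariant to worker count and
  scheduling; the suite checks 1 vs 4 workers.
- **Tolerances**: ε = δ = 1e-6. Both objectives take finitely many values
  but with data-dependent granularity; front points closer than ε in z1 or
  δ in z2 may merge into one. Both are configurable. The solver counts
  lexmin calls (each = 2 MILP solves) and stays within 3·|front| + 2·m + 2
  lexmin calls on the test problems — the budget implied by the splitting
  recursion (every rectangle costs two searches and either closes or pays
  for a new point).

## Synthetic world

The generators state the conditions under which the package is tested:

- Potts ground truth: L = 10, q = 4, dense q×q Gaussian coupling blocks on
  25% of pairs with entry sd 1.0, unit Gaussian fields — a moderately
  coupled regime (conditional logits get comparable contributions from
  fields and couplings), neither frozen nor independent.
- Alignments: vectorized single-site Gibbs chains, 200 burn-in sweeps,
  thinning 5; with zero couplings the sweeps sample the product measure
  exactly, which the marginal test exploits.
- Toy design problems: n = 8–10 positions over a 4-letter alphabet,
  |M_i| ≤ 4, k ≤ 3, 2–3 random-PSSM alleles with protein-context thresholds
  at the 75th percentile (small windows need permissive thresholds for the
  hinge to be active at all), total allele frequency 0.7 — mirroring the
  coverage of the three most prevalent European DRB1 alleles.

What a green test does and does not establish: the i.i.d. Gibbs samples
carry no phylogenetic correlation, the random PSSMs no amino-acid
composition bias, and the toy fronts are small; the tests certify
correctness of the algorithms (exactness of the front, consistency of the
linearization, recoverability of parameters at stated n), not predictive
accuracy on real proteins, which depends entirely on the quality of the
supplied alignment and allele matrices.

## Reporting

- dI = I(design) − I(wt); dE = E(wt) − E(design): positive dE is a
  predicted fitness loss. The convention is written into every TSV header
  rather than assumed.
- Percent changes are 100·(z − z_wt)/|z_wt|; a zero wild-type objective
  falls back to absolute deltas with a flag.
- Landscape percentiles: the design's ΔE is ranked within the single-mutant
  landscape (exhaustive) and sampled double/triple landscapes (seeded,
  budget ≥ 100), using the weak ordering P(ΔE_landscape ≤ ΔE_design), so the
  best possible mutant sits at exactly 100.

## Known limitations

- Runtime grows with |M_i| through the w-variable count
  (Σ_{i<j} |M_i||M_j|); very permissive ζ on long regions will slow the
  MILP. The hinge rows add |H| · (windows touching the region) slacks.
- Fronts with objective gaps below ε/δ merge points; lower the tolerances
  for pathologically flat fronts.
- The mixture-based top-EC caller assumes a unimodal background plus a
  positive tail; heavy-tailed backgrounds push it to the rank-cutoff
  fallback.
- Identity clustering is O(N²L) (chunked); alignments beyond ~10⁵ sequences
  need subsampling upstream.
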