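# deimmune

Population-specific de-immunization of protein therapeutics by exact
bi-objective sequence design.

Therapeutic proteins (coagulation factors, enzymes, non-human antibody
scaffolds) can trigger anti-drug antibodies when HLA class II molecules
present peptides derived from them to CD4+ T cells. Removing predicted
epitopes by point mutation reduces this risk, but mutations chosen by
epitope scores alone routinely break the protein. `deimmune` treats the
problem as it actually is — a trade-off — and computes the *exact Pareto
front* between two objectives over mutants S′ of a wild-type sequence S:

- **Immunogenicity** of a sequence for a target population with HLA alleles
  h ∈ H at frequencies p_h, scored with TEPITOPE-style position-specific
  scoring matrices Φ(h,·,·) over all e_n-mer windows:

      I(S′) = Σ_h p_h Σ_i max(0, Σ_j Φ(h, S′[i+j], j) − τ_h)

  where τ_h is the allele's binding threshold (a percentile of a background
  score distribution); the hinge keeps sub-threshold windows silent.

- **Evolutionary fitness** as the statistical energy of a pairwise
  maximum-entropy (Potts) model of the protein family, inferred from a
  reweighted multiple sequence alignment by l2-regularized pseudo-likelihood
  maximization:

      E(S′) = Σ_{i<j} J_ij(S′_i, S′_j) + Σ_i h_i(S′_i)

  Higher E means a sequence more compatible with the family; the design
  objective minimizes −E(S′).

Candidate substitutions per position are restricted to residues observed in
the family above a frequency threshold ζ, and the design may differ from
the wild type in at most k positions. The resulting bi-objective
mixed-integer linear program (binary residue-choice variables x_{i,a},
pairing variables w_{i,j,a,b} for the coupling terms, continuous hinge
slacks for the epitope windows) is solved to *proven global optimality* for
every front point with a parallel two-phase rectangle-splitting strategy:
lexicographic minimization finds the front's endpoints, an even ε-constraint
slicing of the z1 range seeds the front, and recursive rectangle splitting
between adjacent points finds the rest, closing each rectangle when its
corner points are rediscovered. The MILP backend is HiGHS via
`scipy.optimize.milp` with a zero optimality gap.

The package also provides the surrounding analysis toolbox: alignment gap
filtering and inverse-cluster-size reweighting (Meff), site frequencies and
substitution sets, single/multi-mutant energy effects, evolutionary-coupling
scores (Frobenius norm in zero-sum gauge + average product correction),
EC enrichment, top-EC calling with a Gaussian–lognormal mixture, epitope
scanning and reporting, and seeded synthetic generators (random PSSMs,
random Potts models, Gibbs-sampled alignments) so every component is
testable without external data.

## Worked example

```python
import deimmune as dm

# a seeded synthetic world: 10 positions, 3 alleles, up to 2 mutations
problem = dm.make_toy_problem(dm.ToySpec(n=10, k=2, n_alleles=3, e_n=4, seed=7))
front = dm.solve_pareto(problem, m=4)
print("wild type:", problem.wild_type)
for p in front.points:
    tag = dm.mutation_string(p.mutations) or "wild-type"
    print(f"I = {p.z[0]:7.4f}   E = {-p.z[1]:8.4f}   {tag}")
```

prints

```
wild type: DEEAACCEEA
I =  0.2579   E =  -7.9860   D1E,A10D
I =  0.4167   E =  -4.3117   D1E,C7D
I =  1.1510   E =  -3.8901   D1E,E3A
```

Three mutually nondominated double mutants: reading down, population
immunogenicity I rises while statistical energy E improves — the first
design is the most de-immunized, the last the most family-like, and no
other mutant within two substitutions beats any of them in both
coordinates (the suite verifies this against exhaustive enumeration).

The same computation is available from the shell for real inputs:

```sh
deimmune design --msa family.fasta --target-id FA8_HUMAN --offset 2188 \
    --pssm DRB1_1501.tsv --pssm DRB1_0301.tsv --pssm DRB1_0701.tsv \
    --frequencies europe.json --region 2312:2340 --k 3 -o front
```

which writes `front.tsv` (mutation strings in protein numbering, epitope
counts, dI, dE) and `front.fasta`. `deimmune prepare`, `infer`,
`scan-mutations`, `scan-epitopes` and `fixtures` cover the remaining steps.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a seeded synthetic design problem from scratch, solves it with
the rectangle-splitting solver, verifies the front against brute-force
enumeration, and prints the design report before writing the results file.
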