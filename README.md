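# structmut

Statistical analysis of somatic cancer mutations on protein structures:
mutational-signature-conditioned Monte-Carlo selection tests of structural
metrics, Gaussian-network hinge detection, signature-aware dN/dS, 1D
mutational clustering, sequence-conservation mapping, ensemble flexibility
comparison, and survival analysis — with a synthetic-data module that
generates every input class with known ground truth.

The package is written for structural bioinformaticians asking whether the
somatic mutations observed in a tumor cohort are *selected* for particular
structural properties of a protein — proximity to dynamic hinges, folding or
binding energy (ΔΔG), solvent exposure — rather than merely reflecting the
cohort's mutational processes.

## The core statistic

The null model everywhere is the cohort's trinucleotide mutational signature:
a probability vector over the 96 pyrimidine-centered substitution-in-context
channels (6 substitution classes × 16 flanking contexts), estimated from
CDS-context counts. From it the package builds the **mutation universe** of a
gene — every possible single-nucleotide missense change, weighted by the
signature probability of its context and renormalized.

Given a structural metric *m*(position, ref, alt) and *n* observed missense
mutations, the selection test draws sets of size *n* with replacement from
the weighted universe, computes the mean metric per draw, and reports

&nbsp;&nbsp;&nbsp;&nbsp;p = (b + 1) / (N + 1)

where *b* is the number of the *N* permutation means at least as extreme as
the observed mean (add-one rule; default N = 100,000). Around it sit:

- **GNM hinge detection** — unit springs between Cα atoms within 10 Å
  (1 nm); hinge residues are near-zero components / sign changes of a slow
  nontrivial eigenvector of the Kirchhoff matrix.
- **dN/dS** — obs_N ~ Poisson(μ·r_N·ω), obs_S ~ Poisson(μ·r_S) with
  signature-expected proportions r_N, r_S; 1-df likelihood-ratio test of ω = 1.
- **NMC clustering** — the span of order statistics x(i) < x(j) of n mutation
  positions is referred to Beta(j−i, n−(j−i)+1) with a +1/(L+1) discreteness
  correction and Bonferroni correction over all pairs.
- **SASA** — Shrake–Rupley point counting (960 Fibonacci-lattice points,
  1.4 Å probe) with the buried rule SASA ≤ 20 Å².
- **Ensemble statistics** — Kabsch superposition, RMSD/RMSF over a time
  window, block-resampled Welch t tests of per-residue flexibility, PCA, and
  contact residence times (% frames within 4 Å).
- **Survival** — Kaplan-Meier curves and the two-group log-rank test
  (via lifelines).

## Worked example

Plant a hinge, enrich mutations near it ten-fold, and ask whether the
selection test sees them closer to the hinge than the signature predicts:

```python
import numpy as np
from structmut import simulate, catalog, selection, structure as st

structure, truth = simulate.make_two_domain_structure(seed=11)
enm = st.build_gnm(structure, cutoff=10.0)
hinges = st.find_hinges(st.mode(enm, 1), structure, mode_index=1)

sig = catalog.MutationalSignature.uniform()
gene = simulate.random_coding_gene(structure.n_residues, 99, gene="TOY1")
records, _ = simulate.make_mutation_cohort(
    gene, sig, 50, selection=([n for _, n in hinges.residues], 10.0),
    seed=11, structure=structure)

universe = selection.build_universe(gene, sig)
dist = st.distance_to_residue_set(structure, hinges.residues)
result = selection.monte_carlo_selection_test(
    [r for r in records if r.consequence == "missense"],
    universe, selection.metric_from_positions(dist),
    n_permutations=100_000, seed=0, tail="lower")
```

Output:

```
linker (planted): 31 - 34
hinge residues: [32]
observed mean distance: 9.96 A
expected mean distance: 14.72 A
effect size: -4.77 A
Monte Carlo p (lower tail): 0.00001
```

The planted linker (residues 31–34) is recovered as the hinge; the enriched
cohort's mutations sit on average 4.8 Å closer to it than the signature-only
expectation, and the lower-tail Monte-Carlo p-value rejects the null of no
spatial selection.

A `structmut` command-line entry point wraps the same functionality
(`conserve`, `signature`, `select-test`, `dnds`, `nmc`, `survival`, and
`simulate` subcommands); run `structmut --help`.

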