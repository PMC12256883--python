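# Methods

This note records the models implemented in `structmut`, the conventions and
defaults behind them, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Mutational signature and the mutation universe

A cohort's mutational processes are summarized as a 96-channel signature:
every single-base substitution is collapsed onto its pyrimidine strand
(purine-reference changes are reverse-complemented together with their
flanking bases), giving six substitution classes C>A, C>G, C>T, T>A, T>C,
T>G, each in 16 trinucleotide contexts. Channel index =
`class*16 + 5'base*4 + 3'base` with bases ordered A, C, G, T. Estimation is
by direct context counting over the coding sequence with additive smoothing,

    p_c = (k_c + a) / (K + 96 a),

default pseudocount a = 0.5 so that small cohorts never zero out a channel.
No genome-wide opportunity normalization is applied: the same CDS-context
convention weights both the observed side and the expected side of every
downstream test, so the shared composition bias cancels within a gene. This
is a deliberate simplification relative to full dN/dS machineries (dndscv)
and is the main caveat when comparing absolute signature vectors between
genes of different composition.

Only single-nucleotide substitutions are modeled. Indel/copy-number rows in
input tables are routed to a rejects report with a reason, never silently
dropped. Rows whose stated reference base contradicts the CDS are rejected
loudly; no repair is attempted.

The mutation universe of a gene enumerates all 3L single-nucleotide changes,
keeps the missense ones, weights each by the signature probability of its
context and renormalizes. Terminal CDS positions take their flanking context
from single `flank5`/`flank3` bases carried on the gene record; enumerating
a gene without flanks is an error rather than a guess.

## Monte-Carlo selection test

Null hypothesis: observed missense mutations are an i.i.d. sample (with
replacement — recurrent mutations arise independently in different tumors)
from the signature-weighted universe. The permutation statistic is the mean
of the structural metric over the drawn set (median available); the mean was
chosen because the scientific question is whether the *location* of the
observed metric distribution is shifted. p-values use the add-one rule
p = (b+1)/(N+1), which cannot return 0 and makes the lower-tail p exactly
uniform under the null up to the 1/(N+1) grid. The two-sided default doubles
the smaller tail and caps at 1; "closer than expected" questions use the
lower tail explicitly. Metric or universe coverage failures (an observed
mutation absent from the universe, a universe entry without a metric value)
raise errors listing the missing keys; nothing is imputed.

With a constant metric the permutation distribution is degenerate: the
effect size is 0 and both tail counts equal N, so p = 1 — the documented
convention falls out of the add-one rule with no special casing.

## dN/dS

Per gene, expected nonsynonymous and synonymous proportions r_N, r_S come
from the signature-weighted enumeration of all CDS changes (nonsense counts
as nonsynonymous; stop-loss "other" changes are excluded from both sides).
The model is obs_N ~ Poisson(μ r_N ω), obs_S ~ Poisson(μ r_S); μ is profiled
out, leaving a 1-df likelihood-ratio test of ω = 1 whose statistic reduces to

    2 [ obs_N log(obs_N / e_N) + obs_S log(obs_S / e_S) ],   e = total · r/(r_N+r_S),

with x log(x/e) = 0 at x = 0. The point estimate is
ω = (obs_N/e_N)/(obs_S/e_S). When either observed count is zero the ratio is
recomputed with 0.5 added to all four quantities and the result is flagged
(`fallback=True`). The estimator of log2 ω carries the usual small upward
Jensen bias when obs_S is small (a handful of synonymous events per gene);
the acceptance script quantifies it under ω = 1 and ω = 4. The covariate and
per-context rate structure of dndscv is intentionally out of scope.

## Nonrandom mutational clustering (NMC)

For n mutation positions on a protein of length L, every pair of order
statistics x(i) < x(j) is tested: under a uniform null the fractional span
follows Beta(j−i, n−(j−i)+1). Because residue positions are integers, the
span uses a continuity correction (x(j) − x(i) + 1)/(L + 1); without it,
coincident positions (expected by the birthday effect even under the null)
give span 0 and p 0, and the null any-call rate was measured at ~40% instead
of below α. Recurrent mutations at one residue count as separate order
statistics. Multiple testing is Bonferroni over all n(n−1)/2 pairs —
conservative, in the spirit of the published order-statistics approach —
and significant pair intervals are merged into maximal overlapping cluster
calls carrying the smallest corrected p of their pairs.

## Gaussian network model and hinges

The elastic network is the scalar GNM: Kirchhoff matrix K with K_ij = −1 for
Cα pairs within the cutoff (default 10 Å = 1 nm), diagonal set so rows sum
to zero. The full symmetric eigendecomposition is kept; the number of
eigenvalues below 1e-8·max(1, λ_max) equals the number of connected
components of the contact graph (one zero mode per component), and modes are
indexed 1-based among the nontrivial ones with the sign convention that the
first nonvanishing component is positive. The minimum network size is 2
nodes (the 2-node model has the closed-form spectrum {0, 2}).

A hinge residue is one whose component in a chosen slow mode has magnitude
≤ tolerance (default 0.05 × max |component| — a pure sign-change rule misses
flat near-zero plateaus) or whose sign differs from its predecessor's.
The "slowest nontrivial mode" is the default hinge mode, but the mode index
is an explicit argument because in real proteins a floppy terminus can
occupy mode 1 and push the hinge motion to mode 2; both readings are then
reproducible. Low-confidence termini of predicted structures are not trimmed
by default.

## SASA

Shrake–Rupley point counting on heavy atoms with radii C 1.7, N 1.55,
O 1.52, S 1.8 Å (hydrogens excluded), probe 1.4 Å, 960 Fibonacci-lattice
points per atom. Two non-obvious choices:

- Coordinates are first rotated into a canonical principal-axes frame
  (covariance eigenvectors, third-moment sign convention, right-handed).
  A fixed-orientation point lattice is otherwise only O(1/√n_points)
  rotation-invariant; in the canonical frame any rigidly transformed copy of
  a structure sees an identical lattice geometry, making per-residue areas
  exactly invariant to rotation and translation. The convention is ambiguous
  only for structures with degenerate covariance or vanishing third moments.
- Exactly coincident duplicate atoms (same position and radius) are
  collapsed to a single atom before occlusion; duplicates get zero area.
  Point-on-sphere boundary comparisons at exact coincidence are otherwise
  floating-point lottery.

A residue is "buried" when its summed area is ≤ 20 Å². Interface residues
between two structures are those with any heavy atom within 10 Å of the
partner's heavy atoms (k-d tree, verified against brute force in tests);
distance-to-hinge metrics use minimum Cα–Cα distances.

## Ensemble analysis

Conformational ensembles are multi-model PDB files plus per-frame times (a
sidecar TSV or uniform spacing); native MD trajectory binaries are out of
scope to keep the format surface small. Superposition is Kabsch with the
proper-rotation (det +1) correction; collinear atom subsets are an error.
RMSF is computed over a time window after superposing the window's frames
onto their iterated mean structure (two passes), so the analysis of a
200 ns trajectory's "final 150 ns" is `window=(50, 200)`.

The flexibility comparison splits each window into `n_blocks` contiguous
equal-frame blocks (default 5; remainder frames are dropped), computes
per-block RMSF independently, and compares the two sets of block values per
residue with a Welch t test (unequal variances — the hypothesis itself says
mutant and wild-type variances differ). Zero-variance degeneracies use the
convention: identical block values → t = 0, p = 1; zero pooled SE with a
nonzero mean difference → the smallest positive p.

Known limitation — alignment leakage: a region of strongly elevated mobility
degrades the whole-frame rigid fit and inflates the apparent RMSF of every
other residue by roughly (elevated fraction)/n_residues of the excess
variance. On a 150-residue structure with a 10-residue 3σ segment the
leakage is below the block-test's resolution and specificity stays ≥ 95%;
on very small proteins with large mobile fractions the per-residue test will
flag bystander residues. Superposing on an a-priori stable subset is the
standard remedy when one is known.

PCA operates on superposed, flattened window coordinates via SVD; components
are orthonormal rows, explained variances non-increasing and summing to the
total coordinate variance. Contact residence time is the percentage of
window frames in which a residue pair's minimum heavy-atom distance is
≤ 4 Å.

## Survival

Kaplan-Meier curves and the two-group log-rank test are delegated to
lifelines (product-limit estimator; hypergeometric-variance log-rank with
1 df). Patients censored at an event time are counted at risk at that time.
Assigning the "altered" group (e.g. nonsynonymous mutation OR copy-number
alteration) is a caller decision supported by a labeling helper — which
copy-number calls qualify is cohort-specific and not guessed here.

## Synthetic generators — what they emulate and what they do not

All generators are deterministic under a fixed seed and emit exactly the
formats the readers consume, plus a machine-readable ground-truth sidecar.

- **Two-domain structures**: two compact self-avoiding Cα coils (~3.8 Å
  chain steps) joined by an extended linker along +x. The interdomain span
  is stretched (keeping consecutive steps below the 10 Å cutoff) until no
  domain-domain atom pair is within ~12 Å, so intradomain springs dominate
  and the slowest nontrivial mode flips sign in the linker. Defaults
  30+4+30 residues. With `linker_length=0` the clearance guarantee is
  dropped — a single-domain control with no planted hinge. These are
  Cα-only toys: no side chains, no secondary structure.
- **Mutation cohorts**: draws from the signature-weighted universe;
  optional selection multiplies the weight of entries near target residues
  (within k=5 sequence positions by default, or within 10 Å of the targets'
  Cαs when a structure is supplied — the spatial mode mirrors how
  hinge-proximal enrichment arises on a structure) by `enrichment_fold`
  before renormalizing. `enrichment_fold=1` is the exact null. Mutations
  are independent across draws; co-occurrence within samples and tumor
  phylogenies are not modeled.
- **dN/dS cohorts**: random coding genes (ATG start, no internal stop,
  random flanks); substitutions drawn with relative rates r_S : ω·r_N.
- **Ensembles**: frames are base coordinates plus independent isotropic
  Gaussian displacement per residue (scale σ_i) and a random global rigid
  transform per frame, so superposition is genuinely exercised. The noise
  is frame-independent — there is no autocorrelation, solvent, or
  physics — so passing block-test calibration demonstrates the statistics,
  not MD realism. Under this model a residue's RMSF converges to σ√3.
- **Survival cohorts**: exponential event times, arm-B hazard =
  hazard_ratio × arm-A hazard (default baseline 1/40 per month, median
  ~28 months); censoring is exponential with hazard censor_rate × baseline
  hazard, so `censor_rate=0` means no censoring.

## Problem sizes used by the acceptance script

Eigen-solver agreement at n = 200; hinge recovery over 100 seeds; 500 null
selection tests × 2,000 permutations and 100 power replicates (n_observed
= 50, enrichment 10×); 1,000 neutral genes and 200 ω = 4 genes of 100 codons
with 50 mutations each; 1,000 NMC null simulations (n = 20, L = 380) and 100
hotspot replicates (9 of 30 mutations in residues 182–184); a 2,000-frame
ensemble for RMSF recovery and 2 × 400 frames for the block test on a
150-residue structure; 1,000 null and 100 hazard-ratio-3 survival cohorts of
100 patients per arm. These sizes keep every Monte-Carlo standard error
small relative to the tolerance it is checked against while the whole script
completes in well under a minute.
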