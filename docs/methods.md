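# Methods

## Model

A donor (5' splice) site is represented as the 9-mer spanning the exon-intron
boundary: positions -3..-1 (exonic) and +1..+6 (intronic), letters A, C, G, T.
Given an ensemble of donor sequences, the package fits the maximum-entropy
distribution consistent with the observed one-site marginals f_i(s) and
two-site marginals f_ij(s, t), which is the pairwise Potts / Boltzmann model

    P(S) = exp(-E(S)) / Z,
    E(S) = - Σ_i h_i(s_i) - Σ_{i<j} J_ij(s_i, s_j),

with 36 field parameters h and 576 coupling parameters J (36 unordered
position pairs × 16 letter pairs).  E is a data-driven energy: low energy
corresponds to frequent sequences.  The state space of 4^9 = 262,144 sequences
is enumerated exactly — the partition function Z, likelihood gradients, model
marginals P_i and P_ij, and generative sampling are all exact; there is no
MCMC and no mean-field approximation anywhere.  Internally the enumeration is
organized around a (64, 64, 64) factorization of the state space (three blocks
of three positions), which reduces every full-grid evaluation to a handful of
vectorized passes.

## Fitting

Parameters minimize the L1-regularized negative log-likelihood

    NLL(h, J) + γ Σ |J_ij(s, t)|,
    NLL = log Z - Σ_i f_i · h_i - Σ_{i<j} f_ij · J_ij,

with exact gradients ∂NLL/∂h = P_i - f_i and ∂NLL/∂J = P_ij - f_ij.  Only the
couplings are penalized; the fields absorb the one-site statistics freely.
The L1 penalty drives most couplings to exactly zero, so a fitted model
exposes a minimal set of pairwise interactions sufficient to reproduce the
two-site statistics at the chosen regularization level γ.

The optimizer is a monotone accelerated proximal-gradient scheme (MFISTA):
gradient steps on (h, J) with soft-thresholding of J at γ/L, a backtracking
line search on the local Lipschitz estimate L, Nesterov momentum, and a
monotone safeguard with momentum restart so the objective never increases
across accepted steps.  Fields are initialized at log f_i (zero-sum shifted)
and J at 0, or warm-started from a related model.  Convergence requires all
of: relative objective change < 1e-9, KKT violation on J < 1e-5, and
max_i,s |P_i(s) - f_i(s)| < 1e-5 (tolerances adjustable per call).
Non-convergence is reported in `fit_metadata`, never raised.  The returned
model is in the zero-sum gauge on h (each field row sums to 0); gauge shifts
move all energies by a constant and leave probabilities, energy differences
and orderings unchanged, so absolute energies are only comparable within one
gauge convention.

γ is the per-parameter penalty weight on the per-sequence NLL scale.  On this
scale the soft threshold competes directly with marginal deviations
|f_ij - P_i P_j|: couplings between common letters (products of frequent
marginals) survive much smaller γ than couplings between rare letters.
Support-recovery analyses therefore use γ well below the marginal deviations
the planted couplings induce (γ = 0.005 for couplings of magnitude 0.6 on
near-uniform marginals; γ = 0.01 for the donor-like panels, whose planted
couplings sit on well-populated cells and induce deviations of order 0.03 or
more, while 50,000-sequence sampling noise stays near 0.006).

Target marginals must be strictly positive; estimating them with a
pseudocount (default α = 1 count per position-letter cell, and α/4 per
pair-letter cell so both tables share the denominator N + 4α and remain
mutually consistent) prevents divergent maximum-likelihood fields.  Reporting
statistics (consensus, information content) use α = 0.

## Energetics

Ensembles are scored by E(S); summaries include mean, sd, and 5%/95%
quantiles.  Null references: (a) uniformly random 9-mers — the fully
disordered limit; (b) decoy sequences read around genomic GT dinucleotides (3
nt upstream + GT + 4 nt downstream), sampled with replacement from both
strands, reduced to unique sequences and split by sequence identity against
the annotated donor set into decoy-A (absent from the donors) and decoy-B
(present).  Energy distributions are compared with the two-sided Wilcoxon
rank-sum (Mann-Whitney) test: scipy's exact null for small untied samples,
tie-corrected normal approximation otherwise; the reported statistic is the
signed, tie-corrected normal z.

## Coupling patterns

Each (position, letter) combination is classified by region (exon / intron)
and consensus status (argmax of f_i, ties to the alphabetically first letter
with a logged warning).  Mean couplings are reported per category pair (EC-EC,
EC-IC, IC-IN, ...), averaging over every coupling cell in the category —
including exactly-zero couplings (a `nonzero_only` flag restricts to active
ones).  The per-cell averaging convention is a documented choice; cell counts
per category are fixed by combinatorics (e.g. 3 EC-EC cells, 18 EC-IC cells)
and asserted in tests.

## Phylogenetic signal

The presence/absence of each coupling across species' fitted models defines a
binary character.  Sankoff parsimony computes its minimum substitution cost on
a rooted tree by dynamic programming (arbitrary 2×2 cost matrices, polytomies
supported; unit costs give integer step counts).  The Maddison-Slatkin
randomization permutes tip states uniformly while preserving the
present/absent counts, recomputes the score (vectorized across permutations),
and reports

    p = (1 + #{null ≤ observed}) / (1 + n_perm),

i.e. small observed scores — fewer changes than random placement — give small
p.  Bonferroni correction multiplies by the number of couplings tested.
Constant traits are reported as degenerate with p = 1.

Because the parsimony score is integer-valued, its permutation null has atoms
of several percent and the tie-inclusive Monte-Carlo p is conservative: the
empirical size at nominal 0.05 is about 0.02 for small traits (5-10 present
tips out of 30) and about 0.03-0.04 for balanced traits.  The test never
exceeds its nominal level (P(p ≤ α) ≤ α + 1/(n_perm+1), property-tested); the
conservativeness simply costs power for very unbalanced traits.

## Dendrograms and tree comparison

Species are embedded by their models' vectorized two-site probabilities P_ij
(576 entries; model-derived rather than empirical, since the model is the
smoothed, regularization-consistent estimate — an empirical mode is one flag
away) and clustered by complete linkage on Euclidean distances
(scipy; labels are pre-sorted so distance ties resolve toward the
lexicographically smallest pair).  Comparisons with a reference (time) tree:

- cophenetic correlation: Pearson on the two cophenetic matrices (merge
  heights for dendrograms, patristic distances for trees).  Raw Pearson is
  used despite the scale mismatch: correlation is invariant to the linear
  part, and the rank structure is checked separately in tests.
- Fowlkes-Mallows B_k: both hierarchies cut into k clusters,
  B_k = T_k/√(P_k Q_k); the permutation null relabels one side (an equivalent
  null to shuffling both), vectorized over permutations,
  p = (1 + #{null ≥ B_k})/(1 + n_perm).  An ultrametric reference tree is
  viewed as a dendrogram via complete linkage on its patristic matrix, which
  reproduces its hierarchy exactly.
- entanglement: after a two-sided stepwise untangling heuristic (greedy child
  flips, alternating sides until no flip improves), the normalized L-norm
  (L = 1.5, common tanglegram practice) distance between the two leaf-rank
  vectors; 0 means the orders can be made identical by rotations.

## Synthetic data (what it emulates, what it does not)

All fixtures are pure functions of their seed:

- `make_random_potts`: ground-truth sparse models; fields i.i.d. normal
  (default sd 0.5), n couplings of magnitude `coupling_scale` (default 0.5)
  with random signs at cells drawn without replacement.
- `make_planted_genome`: two-exon genes whose single intron junction spells a
  given 9-mer, half on the minus strand, random A/C/G/T background (no N) —
  exercises coordinate and strand bookkeeping exactly, not genome realism
  (no codon structure, no alternative isoforms, no assembly gaps).
- `make_species_panel`: the comparative study design.  Defaults: 3 groups × 4
  species, 50,000 sequences per species; donor-like field template (consensus
  CAGGTAAGT, near-deterministic +1G/+2T); two backbone couplings shared by
  all species (J_{-1,+5}(G,G) = -0.5, J_{+4,+5}(A,G) = +0.5 — the conserved
  negative exon-intron / positive within-intron consensus pattern); one
  group-specific coupling per group (J_{-1,+6}(G,T) = -0.7,
  J_{-1,+4}(G,A) = -0.7, J_{+3,+5}(G,G) = +0.7 — the divergent pattern);
  normal field jitter (sd 0.05) makes species within a group distinct.  The
  group tree is ultrametric with a trifurcating root.  Planted magnitudes sit
  in the 0.2-0.8 range that γ ≈ 0.01-0.025 shrinkage retains.
- `make_trait_on_tree`: clustered (fill the clade nearest the requested size)
  or uniform random binary tip states.

Passing tests on these panels demonstrates that the pipeline recovers planted
group structure and coupling sparsity under exact model assumptions with
i.i.d. sampling; they do not establish robustness to annotation errors,
within-genome heterogeneity, or phylogenetic non-independence of real donor
ensembles.

## Numerical choices and degenerate inputs

- Letter order A,C,G,T; positions -3..-1,+1..+6; pairs lexicographic; pair
  blocks indexed 4a+b with a at the smaller position.  Couplings are named
  `-1G:+6T` style.
- Exact zeros: couplings shrunk by the soft threshold are stored as exact
  zeros; presence/absence is literal nonzeroness.
- Argmin ties (minimum-energy sequence) break lexicographically; consensus
  ties break alphabetically with a warning.
- Empty ensembles, constant traits, label mismatches, non-positive target
  marginals, and out-of-bounds annotation features raise informative errors
  (or degenerate-result flags where a value is still well-defined).
- Donor windows truncated by contig edges are always dropped (with a logged
  count); N-containing windows are dropped by default.

## Problem sizes used in the shipped analyses

Moment matching is demonstrated at 200,000 sampled sequences; support
recovery on exact marginals of 10-coupling models; the comparative panel at
12 species × 50,000 sequences with 50 replicates in the test suite (10 in
the acceptance script); Maddison-Slatkin calibration at 2,000 replicates of
999 permutations on a 30-leaf tree; Sankoff is verified against exhaustive
minimization on 200 trees of up to 6 tips.

## Known limitations

- The regularization scale is package-specific: γ values are not directly
  transferable from other Potts implementations with different likelihood
  normalizations or penalty conventions.
- Absolute energies are gauge-dependent; only differences and orderings are
  comparable across conventions.
- The L1 fit biases retained couplings toward zero (by roughly the threshold
  γ divided by the local curvature); support and ordering are reliable well
  above the threshold, magnitudes are shrunk.
- Maddison-Slatkin is conservative for unbalanced traits (discrete score;
  see above).
- The untangling heuristic is greedy and not guaranteed to reach the global
  entanglement minimum on adversarial tree pairs.
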