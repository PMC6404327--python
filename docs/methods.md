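# Methods

## Model

An ambiguous genetic code is a row-stochastic matrix P ∈ ℝ^{64×21};
p_cl = P(l|c) is the probability that codon c is translated as label l
(amino acids in alphabetical one-letter order, stop `*` as label 20;
codons ranked lexicographically over A<C<G<T). The unambiguous limit is a
partition of the 64 codons into 21 disjoint, non-empty groups; the two
representations are connected by the degenerate matrix of a partition
(indicator rows) and, in the other direction, by the maximum-likelihood
graph partition (MLGP): c ∈ S_l iff p_cl is the row maximum. The MLGP is
defined only when every label is attained; `mlgp` raises an error naming
the empty labels (this is an existence assumption, not something to be
repaired silently), and `mlgp_lenient` returns the partial assignment for
diagnostics of codes mid-evolution. Row-maximum ties break toward the
lowest label id — ties have probability zero in simulation but must be
deterministic for file-loaded matrices.

## Fitness under misreading

Each scenario defines a codon neighbourhood N(c): c itself plus its
single-nucleotide changes at the scenario's varied positions (M1: third
position; M2: first and second; M3: all three; |N| = 1 + 3·positions =
4/7/10). The varied positions are configuration — the scenario names fix
only the defaults — because "which positions" is a modelling choice, not a
mathematical necessity.

A fitness evaluation draws one representative codon per label from the
posterior P(c|l) = p_cl / Σ_c p_cl (Bayes with a uniform codon prior) and
sums, over all ways of misreading each representative inside its
neighbourhood, the product of conditional label probabilities. Because the
misreading choices are independent across labels, the sum factorizes into
a product of per-label neighbourhood sums; `fitness_forward` uses this
closed form, and the literal forward recursion (`fitness_alpha`) and a
brute-force enumeration oracle (`fitness_direct`, guarded to ≤ 6 labels)
are kept and tested equal to 1e-12 relative. The forward recursion costs
n_labels·|N|² multiply-accumulates (2100 at |N| = 10) versus |N|^21 for
enumeration. Fitness is deliberately stochastic — one fresh draw per
individual per generation — so codes are selected on noisy but biased-high
estimates of their coding probability.

All-zero label columns abort fitness evaluation with an error rather than
being smoothed; the mutation floor (below) prevents them arising in
simulation.

## Evolutionary algorithm

Each generation: (1) every individual has `mutation_rows_per_individual`
codon rows perturbed with iid Normal(0, σ) noise; the perturbed row is
clipped at zero and mapped to `floor + (1 − 21·floor)·normalized`, which
keeps the row exactly stochastic with every entry ≥ the floor; (2) every
individual receives one stochastic fitness evaluation; (3) the next
generation is resampled with replacement proportionally to fitness
(uniformly, with a logged warning, in the measure-zero case that all
fitnesses are zero). There is no elitism. Defaults: σ = 0.05, one row per
individual, floor 1e-6. The mutation magnitude and cadence are modelling
choices (the smallest operator consistent with "perturb one codon's label
distribution"); both are exposed in `EvolutionConfig`.

Initial populations draw each row as 21 iid Uniform(0,1) variates divided
by their sum. This gives mean row entropy ≈ 2.85 nats and whole-matrix
entropy ≈ 182.5 — note this is *not* the Dirichlet(1,…,1) distribution
(symmetric-Dirichlet rows would average ψ(22) − ψ(2) ≈ 2.645 nats/row,
i.e. ≈ 169 per matrix).

Reproducibility: a run's seed feeds a `numpy.random.SeedSequence`;
replicate i uses seed + i on an independent stream, so any replicate can
be re-executed bit-identically in isolation. Trajectories log mean
population entropy and best/mean single-draw fitness at generation 0,
every `log_every` generations, and at the final generation. Plot smoothing
uses a centered running mean; no model-based curve fitting is applied.

## Measures

* Entropy H(P) = −Σ p_cl ln p_cl (sum of per-row Shannon entropies,
  0·ln 0 := 0). Natural log throughout: it is the base under which random
  initial codes measure ≈182, the scale on which results are quoted.
* Coding strength ψ(S_l) = mean of p_cl over the group, Ψ = 21-group mean.
  The MLGP is not in general a global or even local maximizer of Ψ under
  single-codon moves between *unequal*-size groups (a swap into a smaller
  group can raise Ψ); the provable property — swapping two codons between
  equal-size MLGP groups never increases Ψ — is the one asserted in tests.
* Conductance: the codon graph joins codons at Hamming distance 1; it is
  9-regular with 288 edges. φ(S) = crossing edges / 9|S|, kept as an exact
  `Fraction` (the published tables print exact fractions; floats are
  rendered at 4 decimals only at the output boundary). The k-size minimum
  φ_k(G) is found exhaustively for k ≤ 4 (all C(64,k) subsets, with a
  sound early stop when the trivial C(k,2) internal-edge bound is
  attained: φ_1 = 1, φ_2 = 8/9, φ_3 = 7/9, φ_4 = 2/3). For k > 4 a greedy
  max-internal-edge search from every seed vertex reports the best set
  found, explicitly flagged as an upper bound (`exact=False`); C(64,6) ≈
  7.4·10⁷ subsets is beyond a sensible enumeration budget and the greedy
  bound reproduces the known optimal size-6 structure (a four-codon block
  with an attached pair, φ = 2/3).

## Bundled reference codes

The best evolved code per scenario from a full-scale campaign (50
replicates × 1000 individuals × 50,000 generations) ships as package data:
the 21 codon groups plus the published per-group ψ and φ values.
`reproduce_tables` recomputes every group's φ from the graph, the k-size
minima, Φ and Ψ, and writes published-versus-computed comparisons. One
published value is provably a misprint: the M2 code's group
{CAA,CTA,CTT,CTC,CGA,CCA} is printed with φ = 35/54, but for any size-6
set vol = 54 and crossing = 54 − 2·internal is even, so 35/54 is
impossible; the true value is 36/54 = 2/3, which moves the code's average
conductance from the published 0.8580 (an average over the misprinted
fraction) to 487/567 ≈ 0.8589. Likewise the published count of thirteen
non-optimal groups for that code recomputes to 10. The package reports the
recomputed values and flags the discrepancies rather than reproducing
them.

## Problem sizes and what the tests show

Deterministic statistics (conductances, coding strengths, neighbourhoods,
cost model) are exact and cheap. Stochastic checks run at desk scale:
1,000 random matrices for the initial-entropy estimate, and an
evolutionary study design of population 200 × 2,000 generations × 10
replicates per scenario. At this scale the entropy decline from ≈182 to
≈155 is reproduced robustly in every replicate of every scenario, and the
M1-below-M3 final-entropy ordering holds in replicate means — but the
between-model separation is small compared with the within-model spread,
because much of the desk-scale entropy decline comes from the concavity
bias of row mutation (identical across scenarios) rather than from
scenario-specific selection, which dominates only on far longer horizons.
Full-scale end states (e.g. near-unambiguous M1 codes with H_av ≈ 5)
require the 50,000-generation setting and also depend on mutation
parameters that the defaults here only exemplify; the synthetic dynamics
therefore demonstrate the direction and ordering of the effect, not its
published magnitudes.

The generator emulates iid uniform translational ambiguity with no
codon-usage bias, no transition/transversion asymmetry and unweighted
neighbourhoods; passing tests say nothing about codes evolving under
weighted misreading or biased initial conditions.

## Degenerate inputs and numerical choices

Row-sum tolerance on I/O is 1e-9; rows are kept verbatim when within
1e-12 of 1 (so write/read round-trips are bit-exact with 17-significant-
digit TSVs and `float_precision="round_trip"` parsing) and renormalized
otherwise. Conductance of the empty or full codon set is a domain error;
partitions with empty groups are rejected at construction. Fitness
underflow is not a concern: with the default floor, F ≥ (4e-6)^21 ≫ the
double-precision minimum.
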