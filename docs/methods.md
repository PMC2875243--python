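# Methods

## The model

An alignment of protein sequences *A* (length *m*) and *B* (length
*n*) is identified with a monotone route on the (m+1)×(n+1) lattice:
unit right, down and diagonal steps from (0,0) to (m,n), each emitting
one column *u* ∈ Γ\* = (Ω ∪ {gap})² minus the gap–gap pair. The
objective assumes the column chain is first-order Markov and scores a
route as

    D(R) = Σ_k (1−ε)·c(u_k) + Σ_{k≥2} ε·t̂(u_{k−1}, u_k),

a convex mixture of a per-column difference and a per-transition
difference. `align` minimizes D over all routes and returns the
minimizing alignment; `route_difference` evaluates D for any given
alignment, and the two agree by construction (asserted in tests to
1e−9).

### Per-column difference c(u)

Substitution scores s(a,b) from a standard matrix (BLOSUM62, PAM250,
GONNET250 — loaded through biopython, where GONNET250 is the 1992
Gonnet 250-PAM matrix) are mapped to differences by the affine
normalizing function

    f_s(x) = (s_max − x) / (s_max − s_min),  clamped to [0, 1],

with s_max the largest matrix entry and s_min the smallest value of
the normalization domain. The domain is widened to cover the raw gap
scores the user supplies, so `w_open = f_s(gap_open)` and
`w_extend = f_s(gap_extend)` always land in [0,1] with
`w_extend ≤ w_open` when `gap_extend ≥ gap_open`. Gap columns cost
`w_open` on the first column of a run in their own direction and
`w_extend` on each further column (affine gaps); terminal gaps are
penalized like any others, making this a true global alignment.
Defaults: ε = 0.775, gap_open = −11, gap_extend = −0.3, GONNET250.

### Transition quantity t̂(u, v)

From conditional probabilities p(v|u) of observing column *v*
immediately after column *u*, set t(u,v) = log p(v|u) and normalize
per source row:

    t̂(u,v) = (t_max(u) − t(u,v)) / (t_max(u) − t_min(u)),

over successors with p > 0. The most probable successor gets 0, the
least probable 1. Degenerate rows (all positive probabilities equal)
are uninformative and map to 0; successors with p = 0, and every row
never observed in training, get the conservative maximal difference 1.
A neutral all-zero matrix is substituted when no trained matrix is
supplied, which reduces the objective to the classical normalized
substitution/gap score at any ε.

### Estimation from reference alignments

Training input is a corpus of pairwise reference alignments (one
aligned-FASTA file of two records each). To damp redundancy, a
degapped sequence occurring N times across the corpus carries weight
N^(−1/2); an alignment of A with B adds (N_A·N_B)^(−1/2) to the count
of each of its adjacent column pairs. Counts are order-symmetrized —
((a,b)→(c,d)) is always counted together with ((b,a)→(d,c)) — so the
measure, and hence the aligner's objective, is invariant under
swapping the two input sequences. Probabilities use additive
pseudocount smoothing (default 1.0) over the full 440-pair successor
space; smoothing spreads mass within observed rows but does not create
support for unobserved ones, which keep the default fill t̂ = 1.

### Dynamic program

A three-state Gotoh-style recursion over states V = (a_i, gap),
M = (a_i, b_j), H = (gap, b_j). Because the state of a cell fixes the
symbols of the column that produced it, the transition quantity
between predecessor and current column is available in O(1) and the
whole DP fills exactly (m+1)(n+1) lattice points (instrumented and
asserted). Opening vs extending a gap is decided by the predecessor
state. The first column of a route carries no transition term (it has
no predecessor). Edges are handled by the same recursion started from
D_M(0,0) = 0 with all other border states at +∞. Ties prefer the
diagonal state, then vertical, then horizontal, both in the minimum
and in traceback, giving a deterministic alignment. Accumulation is in
double precision; test comparisons use 1e−9 absolute tolerance. Empty
inputs return the all-gap alignment at its edge cost (empty/empty
returns D = 0).

### Q score and identity bins

The Q score of a test alignment against a reference is the fraction of
the reference's aligned residue pairs (two residues sharing a column,
over all sequence pairs for N > 2) that the test reproduces; 1 when
the test equals the reference, 0 when no pair coincides. Percent
identity of a pairwise reference is the share of identical-residue
columns among columns pairing two residues — a denominator that is
stable under terminal-gap padding. Summaries bin reports into the
conventional half-open identity ranges [0,15), [15,30), [30,45),
[45,100] plus an "All" aggregate.

## Synthetic data

The generators in `mtrap.simulate` make every component testable
offline and reproducible from a seed (one RNG stream per
(seed, generator-name), so adding a generator never shifts existing
streams).

* `random_sequences`: i.i.d. residues, uniform composition unless
  specified.
* `mutate_pair`: per-residue substitutions (uniform over the other 19
  letters) at a configurable rate, indels starting with probability
  `indel_rate` per position, insertion/deletion equally likely,
  geometric lengths (mean 2 by default — short enough to exercise both
  gap opening and extension). Returns the true alignment as ground
  truth plus the degapped descendant.
* `synthetic_markov_corpus`: samples column chains from a prescribed
  conditional distribution over symbol-pair labels, for checking that
  the estimator recovers known transition probabilities.

What this emulates — and does not: the mutation model has no rate
heterogeneity across sites, no realistic substitution preferences
(mutations are uniform, not PAM-like), and no evolutionary time scale;
the Markov corpus has, by design, exactly the first-order dependence
the measure assumes. Passing tests therefore demonstrate correctness
of the algorithms (optimality of the DP, consistency of the
estimator, scoring arithmetic), not alignment accuracy on real
structure-based benchmarks, which require external databases.

## Problem sizes and verification

The estimator's parameter-recovery check runs on a reduced 3-residue
alphabet (15 valid symbol pairs, swap-symmetric truth) with 100,000
adjacent-pair observations (500 alignments × length 201), where each
conditional row is resolved to well under the 0.02 max-error bound; a
full 440-pair space cannot be resolved at that sample size and is
covered instead by the structural checks (row normalization, range,
symmetrization, weight invariance). The aligner is validated against
two independent oracles: exhaustive route enumeration (200 random
instances with m, n ≤ 4 and ε ∈ {0, 0.5, 0.775, 1}, route counts
checked against the lattice-path recursion) and, at ε = 0, a
textbook cost-minimizing affine-gap aligner. End-to-end pipeline tests
use corpora of 6–8 alignments of length 50–60 and pairs of length
60–120, enough to exercise every code path while keeping the default
suite fast.

## Design choices and limitations

* Support semantics: "observed" means positive raw weighted count;
  pseudocount smoothing never promotes an unobserved source row into
  the support. This keeps never-seen contexts maximally penalized
  rather than silently uniform.
* Identical alignment members ("A aligned with itself") count as two
  occurrences of the sequence, per the exact-string multiplicity rule.
* The order-symmetrization of counts is a package choice made so that
  align(A, B) and align(B, A) have equal objectives; estimation
  without it would make the measure order-dependent.
* Ambiguity codes (B, Z, X) are rejected in sequences; the measure is
  defined on the 20-residue alphabet. '*' in input files is rejected
  rather than interpreted as a gap.
* Only global pairwise alignment is implemented: no local alignment,
  no banded or linear-memory variants, no multiple-alignment
  construction (the Q scorer handles N-sequence alignments, but
  nothing builds them).
* The DP is pure Python and comfortable for sequences of a few hundred
  residues; very long sequences would want a compiled kernel.
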