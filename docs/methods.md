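# Methods

This note records the model, the defaults and the design choices behind
`hoppi`, and what the synthetic studies do and do not demonstrate.

## Model and assumptions

The method rests on homology transfer: if homologs of two query proteins
are known to interact, or sit near each other in a known PPI network, the
queries are more likely to interact.  Three features capture this.

**F_Seq.**  Similarity hits for each query (against the database of
training-set sequences) are searched for a hit pair that is a known
interacting pair; the pair minimizing the Euclidean norm of the two
e-values wins.  The permissive e-value cutoff of 1e2 deliberately admits
partial matches.  Each side is summarized by its e-value and by *mincov*,
the count of positive-scoring alignment columns divided by the length of
the longer of the two sequences — a symmetric coverage measure that
penalizes matches covering only a fragment of either protein.  When no
interacting template is found the pair receives (1e2, 0, 1e2, 0), i.e. the
worst admissible e-value and zero coverage; these sentinels are ordinary
feature values and are discretized like any other.  All hit rows are
retained (no best-hit-per-subject filtering): the minimization itself
selects among them.  Ties on the norm break by smaller e_A, then larger
mincov_A + mincov_B, then lexicographic template ids, so the search is
deterministic.  Self-hits are not excluded; in evaluation an optional
filter (off by default) drops target pairs for which an interacting
template with both e-values exactly 0 exists, isolating performance on
pairs that are not trivially recoverable from identical sequences.

**F_Dom.**  Domain-pair propensities are natural-log ratios of
class-relative frequencies of unordered domain pairs among training
pairs.  Domain pairs are built from *sets* of distinct domains per protein
(a domain repeated within one protein counts once), matching the
symmetric, type-level reading of a domain pair.  The raw ratio is
undefined whenever a pair never occurs among negatives — a common event —
so an additive pseudocount α (default 1) is applied to every stored
pair's count in both classes, with denominators enlarged by (number of
stored pairs)·α.  The pair score is the *mean* propensity over all
formable domain pairs; pairs unseen in training contribute 0 but count in
the denominator, since 0 is the no-evidence value of the log-odds scale.
Pairs where either protein lacks domains score 0.

**F_Net.**  The training PPI network has one unit-weight undirected edge
per positive training pair (self-pairs become self-loops; only constant
weights are implemented — the weight field exists for future schemes).
For each hit pair (p_A, p_B) at the stricter cutoff of 1e-3 the Dijkstra
shortest-path weight is computed and the minimum over combinations is the
feature; −1 encodes "no path anywhere".  SPW(x, x) = 0 for any node
present in the network — the zero-length path — without requiring a
self-loop edge: an SPW of 0 therefore means the two queries share a
homolog that participates in known interactions.

## Order invariance

A pair has two encodings differing by the swap of the F_Seq halves.  The
package fixes the reference point X1 = (evalue_A=0, mincov_A=1,
evalue_B=100, mincov_B=0), whose associated normal rn ∝ (−100, 1, 100, −1)
is anti-symmetric under the swap; an encoding is kept iff rn·F_Seq ≥ 0,
otherwise swapped.  Because rn is orthogonal to every swap-symmetric
vector the midpoint term vanishes and only the sign of rn·F_Seq matters —
the e-value scale dominance within rn is irrelevant.  A fixed constant
reference (rather than an arbitrary training pair) makes models
reproducible and serializable.  At rn·F_Seq = 0 the two encodings are
mirror images through the hyperplane and the input orientation is kept;
combined with canonical pair storage (idA ≤ idB) the pipeline output is
fully deterministic.  Canonicalization precedes discretization, so the
split points are fitted on the selected half-space representatives.

## Discretization

Each feature is discretized by recursive binary splitting minimizing
class entropy, a cut being accepted only when its information gain
exceeds (log2(N−1) + Δ)/N with Δ = log2(3^k − 2) − [k·H(S) − k1·H(S1) −
k2·H(S2)].  Candidate cuts are midpoints between adjacent distinct values
that are class boundary points (adjacent value groups not pure in the
same class) — the standard restriction, which provably contains the
entropy-optimal cut.  Ties in gain resolve to the smallest cut value.  A
feature with no accepted cut keeps a single bin.  Values equal to a split
point fall in the right (upper) bin.  Split points and the reference
orientation serialize to JSON so train and predict runs are
bit-compatible.

## Classifier

The AODE and its Laplace-smoothed estimates are implemented exactly as
printed in the README.  Products are accumulated in log space (with
`logsumexp` over parents); with six features this equals the naive
product to ~1e-12, and it is robust if more features are ever added.
Every known feature serves as a parent by default: no minimum
parent-frequency cutoff is applied (a configurable `parent_min_count`
exists for the textbook m ≥ 30 rule).  MISSING features are skipped in
both the sums and the products and are excluded from the m_i / m_ij
counts at fit time; the pipeline itself never produces MISSING values
(sentinels are real values), but the support is kept because the count
definitions reference it.  k = 2 is carried explicitly in the smoothing
denominators.  The Naive Bayes baseline reuses the same smoothed joints,
score(c) = P̂(c)^(1−n) Π_i P̂(c, f_i) with P̂(c) = (N_c+1)/(N+k), which
makes the single-feature AODE and NBC exactly identical — the expected
degeneracy of averaging over one parent.

## Evaluation protocol

Negatives are drawn uniformly from the distinct unordered non-positive
pairs over the protein universe (default: the proteins of the positive
set), exactly ratio·|positives| of them, seeded; the sampler enumerates
candidates when the request is a large fraction of the universe and
rejection-samples otherwise, both uniform.  Folds are stratified by class
and keyed on pair identity, so the partition is invariant to input file
ordering.  Per fold, the template positive set, propensity table,
network, discretization scheme and classifier counts are all rebuilt from
the training folds — the only reading that prevents a test pair's own
edge or template from leaking into its features — and the fold records a
programmatic audit (count of test pairs present among that fold's
templates or edges, asserted zero in tests).  ROC curves collapse tied
scores into single threshold steps; AUC is the trapezoidal integral,
which then equals the Mann–Whitney concordant-pair statistic with half
credit for ties.  Partial AUC up to FPR ≤ x is the raw partial area
divided by x, so a perfect model scores 1.0 at every cutoff (no McClish
transformation).  MCC returns 0 when any denominator factor vanishes;
F-measure returns 0 when TP = 0.  Threshold selection scans the distinct
score values and returns the smallest maximizing the F-measure.  Method
comparison uses an unpaired equal-variance two-sample t-test on per-fold
AUCs (the pairing structure across folds is ambiguous in general; the
unpaired test is the conservative choice), returning 1 when both samples
are constant and equal.  The SPW distribution analysis tallies, per fold
and class, the lowest SPW of each held-out pair at exact values up to a
configurable cap (unit weights make these integers), then "≥ cap", plus
NP for no path, reporting per-class percentages and mean per-fold counts.

## Synthetic data

The generator emulates the *interfaces* the pipeline consumes, not
sequence evolution: proteins are grouped into homolog families (default
size 2) anchored to templates connected in a base network
(Erdős–Rényi-style with mean degree 4 by default; preferential-attachment
optional because real PPI networks are heavy-tailed and SPW distributions
depend on topology).  The hit table links each protein to its family
members — a self-hit at e-value 0 plus cross-hits with e-values
log-uniform in (1e-50, 1e-10) and coverages in (0.6, 0.95) — mimicking a
search of each protein against the full training database.  With
probability `signal_strength` a positive pair is drawn across a random
base-network edge and proteins carry their template's characteristic
domain, so all three features become informative; at signal 0 labels are
independent of everything and cross-validation must sit at chance.
Negatives use the evaluation sampler at `neg_ratio` per positive.

Default study sizes (200 proteins, 300 positives, 50 negatives per
positive) are a deliberate desk-scale design: large enough that ten-fold
CV has ~30 positives per test fold and the no-signal AUC concentrates
near 0.5, small enough that a full double CV completes in about a minute.
What passing tests show: the pipeline recovers a planted homology signal
without leakage and is exactly order-invariant and oracle-consistent.
What they do not show: performance on real proteomes, whose hit tables
contain promiscuous domains, varying family sizes, and negatives that are
merely unlabeled rather than true non-interactions.

## Numerical and degenerate-case conventions

* mincov is clipped to [0, 1] (gapped alignments can exceed the shorter
  length).
* e-value 0 is a legal stored value (identical-sequence hits).
* fnet is ≥ 0 or exactly −1; hit subjects absent from the network are
  simply unreachable.
* Empty domain sets contribute nothing to the propensity table and score
  0 at prediction.
* ROC requires both classes; single-class fold inputs raise.
* All randomness flows through `numpy.random.default_rng` seeds; the
  synthetic generator is a pure function of its config (which includes
  the seed), and fixture files are byte-identical across runs.
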