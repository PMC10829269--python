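# Methods

## Model

A protein is represented only by its set of functional-domain terms
(InterPro-style accessions, treated as opaque IDs — no parent/child hierarchy
expansion). The working assumption is that domain content is strongly
class-associated: a term carried predominantly by, say, hydrolases in the
training set is evidence that a new carrier is a hydrolase.

Training estimates, for each term *t* in the training vocabulary, the counts
*N(t)* (annotated training proteins) and *N_j(t)* (those carrying class *j*;
a multi-label protein contributes to every one of its classes but to *N*
once), and the ratios *R_j(t) = N_j(t)/N(t)*. Because every training protein
has at least one label, Σ_j N_j(t) ≥ N(t) and 1 ≤ Σ_j R_j(t) ≤ L; these
invariants are asserted on every profile build. A protein is encoded as
X_j = max over its in-vocabulary terms of R_j(t). The max (rather than a mean
or sum) makes a single strongly class-exclusive term decisive, matches the
intuition that one diagnostic domain suffices, and makes the encoding monotone
in the term set: adding terms never lowers any component.

Classification uses a random-k-labelsets ensemble: *m* uniform size-*k* label
subsets (the whole collection is redrawn, advancing the seeded stream, until
every label is covered; duplicates are allowed — with k = L the full labelset
is the only possible subset), one Label-Powerset classifier per subset over a
pluggable base learner, per-label vote-fraction aggregation with threshold
0.5 (positive at equality), and an argmax fallback (ties to the lowest label
index) so predicted labelsets are never empty — the overlap measures are
undefined when both the true and predicted sets are empty, and every protein
in scope has at least one class.

## Degenerate inputs and numerical conventions

- Terms unseen in training are skipped at encode time (their ratios are
  undefined); a protein with no known terms encodes to the zero vector rather
  than erroring — such proteins are merely unreliable, and a classifier must
  still emit something. The count of known terms is carried alongside the
  vector so callers can flag low-evidence predictions.
- No smoothing is applied to the ratios by default (raw proportions); an
  additive-pseudocount hook exists (`R_j = (N_j + s)/(N + sL)`) but defaults
  to s = 0.
- An LP subproblem in which only one labelset pattern was observed is fitted
  as a constant predictor, not an error.
- MCC with a zero denominator is defined as 0; precision/recall with empty
  denominators are reported as 0 with an explicit `*_defined = False` flag.
- AUROC is the mid-rank Mann–Whitney statistic (undefined → NaN for
  single-class truth); AUPR is average precision (step-wise precision times
  recall-increment); a trapezoid variant is exported as well because curve
  integrators differ across toolkits, and the score source for the curves
  (class-probability mass when the base learner exposes probabilities, hard
  vote fractions otherwise, with a logged warning) is recorded in every
  report.
- Ratios are stored at full float precision; tabular reports round to 4
  decimals.

## Cross-validation and leakage

The encoding depends on the training set, so the profile must be rebuilt
inside every fold from that fold's K−1 training parts only; this is mandatory
and not configurable (a hidden `--leaky` debug flag exists solely to
demonstrate the optimistic bias and is loudly labelled). Folds are assigned
before any model fitting and reused across a grid search so configurations
are compared on identical partitions.

Two partition schemes: *general* (uniform random, fold sizes within 1) and
*stratified* (L single-class groups, one group for a designated label pair —
default transferases+hydrolases, the dominant shared pair in human enzymes,
and configurable because it is a property of the data at hand — plus a
remainder group; each group is dealt into K near-equal parts and part i of
every group forms fold i). Grid search ranks by mean overlap accuracy,
breaking ties by absolute true (descending) then absolute false (ascending).
Per-fold mean and sample standard deviation (ddof = 1) are reported; wall
time is recorded on the report object but excluded from the canonical JSON so
identical (config, seed) runs serialize byte-identically.

## Base learners

Random forests and SVMs are provided through scikit-learn behind a
fit/predict(/predict_proba) contract; any conforming learner plugs in. The
four SVM kernels are polynomial (integer exponent), normalized polynomial
(K/√(K_xx·K_yy)), RBF (γ), and the Pearson VII (Puk) kernel implemented as a
custom kernel function with shape parameters σ = ω = 1.0 by default (the
reference toolkits do not document their defaults; both are configurable).
SVMs without probability estimates fall back to hard-vote curve scores with a
warning.

## Seeding

Every stochastic component (labelset sampling, each LP model, fold
partitions, the corpus generator) derives its seed from one master seed via
`numpy.random.SeedSequence`, so any run is reproducible end to end from a
single integer.

## Synthetic data

The generator emulates the statistical regime of curated enzyme corpora: L=7
classes with sizes proportional to the human benchmark breakdown
(288/1080/747/113/80/86/51), multiplicity degree ≈ 1.03 via a 3 % second-label
rate, per-protein term counts from a truncated geometric with mean ≈ 5.7 on
[1, 25] (most proteins under ten terms), per-class vocabularies of 50 terms of
which 20 % leak to one other class, 25 shared (class-agnostic) terms, and 5 %
uniform term-replacement noise. These defaults were fixed once as the
simulated study conditions.

A fixed worked example (8 proteins, 3 classes, 5 terms) is shipped for hand
auditing. Its training profile and encodings, derived by hand from the
counting rules and asserted in the test suite:

| term | N | N₁,N₂,N₃ | R₁,R₂,R₃ |
|---|---|---|---|
| IPR000001 | 3 | 3,0,1 | 1, 0, 1/3 |
| IPR000002 | 3 | 1,2,0 | 1/3, 2/3, 0 |
| IPR000003 | 2 | 1,2,0 | 1/2, 1, 0 |
| IPR000004 | 2 | 0,0,2 | 0, 0, 1 |
| IPR000005 | 2 | 1,0,2 | 1/2, 0, 1 |

| protein | terms | labels | X |
|---|---|---|---|
| p1 | 1 | {1} | (1, 0, 1/3) |
| p2 | 1,2 | {1} | (1, 2/3, 1/3) |
| p3 | 2 | {2} | (1/3, 2/3, 0) |
| p4 | 2,3 | {2} | (1/2, 1, 0) |
| p5 | 3 | {1,2} | (1/2, 1, 0) |
| p6 | 4 | {3} | (0, 0, 1) |
| p7 | 4,5 | {3} | (1/2, 0, 1) |
| p8 | 1,5 | {1,3} | (1, 0, 1) |

(term column abbreviates IPR00000x to x). Label-powerset transformation over
the full label set maps the five observed labelsets {1}, {2}, {1,2}, {3},
{1,3} to five powerset classes.

What it does **not** emulate: real InterPro term co-occurrence topology,
term-hierarchy structure, heavy-tailed term frequencies, or sequence-level
redundancy. Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted class signal — not the accuracy attainable on
real annotation databases, which requires the real domain tables.

The recovery experiment used by the test suite and the acceptance script runs
on the *exclusive-signal* configuration — exclusivity 1, no annotation noise,
and no shared vocabulary — because the generator only guarantees separability
when every term is class-determining: with a shared pool, a protein whose few
terms are all shared carries no class signal by construction. Problem sizes
(n = 1000 proteins, 10 folds, 100-tree forests, k = 7, m = 10) were chosen as
the smallest corpus at which per-fold statistics are stable; measured overlap
accuracy is ≈ 0.99 and moves by less than 0.01 across fold seeds.

## Known limitations

- The encoder ignores term frequency within a protein (sets, not bags) and
  any inter-term dependence; two terms individually weak for a class but
  jointly diagnostic are not captured by the per-term max.
- Published headline accuracies on human/yeast enzymes are not reproduced
  here: they require the external enzyme lists and the full InterPro release
  those studies used, plus the exact internals of their Java toolchain's
  learners. The package reproduces the method and protocol, and verifies them
  on synthetic corpora and hand-computed examples.
- `stratify_by_annotation_count` breaks count ties by input protein-ID order
  (stable sort); group membership at the boundary is therefore deterministic
  but arbitrary among tied proteins.
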