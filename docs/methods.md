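# Methods

## Problem and model family

`targetbn` classifies instances described by discrete attributes
X = (X1..Xn) into a class C by maximum posterior under a Bayesian network
classifier: a DAG over {C, X1..Xn} plus conditional probability tables
(CPTs).  Four members of the family are implemented, in increasing order of
structural expressiveness:

* **Naive Bayes (NB)** — 0-dependence: P(x, c) = P(c) ∏ᵢ P(xᵢ|c).
* **TAN** — 1-dependence: a Chow–Liu maximum-weight spanning tree over the
  attributes with edge weight I(Xi; Xj | C), giving each attribute one
  attribute-parent besides C.
* **KDB** — k-dependence: attributes sorted by descending I(Xi; C); the
  attribute at position i takes min(i−1, k) earlier attributes as parents,
  chosen by largest I(Xi; Xj | C).  Attribute-edge count: nk − k(k+1)/2.
* **UKDB** — the unrestricted extension.  The k attributes with the largest
  *sum* of pairwise CMI, SCMI(Xi) = Σⱼ I(Xi; Xj | C), form a Markov-blanket
  parent set X_p that is parent of C and candidate parent of everything
  else.  Classification uses P̌(x, c) ∝ P(c|x_p) ∏ᵢ P(xᵢ|Π̌ᵢ, c), where
  every non-X_p attribute has exactly k attribute-parents chosen by CMI
  from X_p and earlier attributes (the remaining attributes are ordered by
  descending SCMI).  P(x_p) is never parameterized: it cancels in the
  argmax.

### Target learning (the lazy sub-model)

UKDB is an ensemble of two sub-models sharing one learning scheme:

* **UKDB_T** is learned once from the training set using MI/CMI.
* **UKDB_P** is re-learned for *each prediction target* from the
  value-level (local) analogues

      I(xi; C)      = Σ_c P(c, xi) log [ P(c, xi) / (P(c) P(xi)) ]
      I(xi; xj | C) = Σ_c P(xi, xj, c) log [ P(xi, xj|c) / (P(xi|c) P(xj|c)) ]

  with SCLMI(xi) = Σⱼ I(xi; xj | C) replacing SCMI.  Because the target is
  unlabeled, one *pseudo instance* per class (the target's attribute values,
  unit weight) is added to the count cache before computing LMI/CLMI, so
  values unseen in training still have defined statistics.  Attributes whose
  value is missing in the target are excluded from the lazy structure
  entirely — no imputation noise enters it; if fewer than k+1 values are
  present, k degrades with a warning.

The final posterior is the uniform average
P̂(c|x) = [P(c|x, UKDB_T) + P(c|x, UKDB_P)] / 2.  Nonuniform weighting is
deliberately out of scope.

## Probability estimation

* **Information measures** use pure maximum-likelihood probabilities, no
  smoothing: smoothing would bias the rankings, and the value-level
  decomposition identities (Σ LMI = MI, Σ CLMI = CMI) then hold exactly.
  Each measure derives all of its marginals from its own contingency table,
  which keeps those identities exact even when missing cells make the
  per-attribute row counts differ.
* **CPTs** use Laplace smoothing with pseudo-count α (default 1); α = 0
  gives MLE with a uniform fallback on unseen parent configurations.  The
  pseudo instances are *not* added to the CPT counts: they exist to make
  the value-level structure statistics well-defined, and Laplace smoothing
  already covers unseen values in the conditionals.  All scoring is in the
  log domain.
* **Logarithm base** defaults to 2 (scores in bits) and is configurable;
  changing the base rescales every measure by ln 2 and provably leaves all
  rankings, structures and posteriors unchanged.

For the lazy sub-model only the conditionals at the target's own values are
needed, so they are computed by direct config counting against
class-partitioned training rows (for k = 1 this is equivalent to reading
the pair-count cache) rather than materializing full tables per instance.

## Numerical and tie-break choices

* Every ranking (MI order, SCMI, SCLMI, parent choice, spanning-tree edge
  order, argmax prediction) breaks ties by ascending attribute/class index,
  so all learned structures and predictions are reproducible.
* The TAN tree is built by Kruskal on descending CMI and rooted at the
  attribute with maximal MI with the class; the tree itself is
  direction-free, the rooting only fixes a valid factorization.
* 0·log 0 := 0 throughout; pointwise MI/CMI return −∞ with a warning when a
  probability in the ratio is zero.
* Posterior factors whose child or parent values are missing are skipped;
  a query where every factor is skipped returns a uniform posterior with a
  warning.
* Pair counts are stored once per unordered attribute pair, so cache
  construction is O(N·(n·v)² ·m)-bounded in time and memory and structure
  learning never rescans the data.

## Evaluation protocol

Repeated stratified k-fold cross-validation (default 10 folds × 20
rounds).  Per training fold: mode/mean imputation (statistics from that
fold only) and minority-class oversampling by seeded replication until
class counts are equal.  Test folds are never oversampled; test-time
missing values are imputed with the *training* modes for NB/TAN/KDB and
the training-set UKDB sub-model, while the lazy sub-model skips them.
Metrics: zero-one loss per fold, F1 = 2TP/(2TP+FP+FN) on the minority
(positive) class, and a threshold-sweep ROC with trapezoid AUC (tied
scores grouped).

Bias–variance uses the Kohavi–Wolpert zero-one decomposition over repeated
random 50/50 splits (default 10 repeats): per instance, with empirical
prediction distribution p and true class y, bias = ½ Σ_c(1[c=y] − p_c)²
and variance = ½(1 − Σ_c p_c²); with deterministic labels bias + variance
equals the estimated loss exactly.  Comparisons across datasets use
Win/Draw/Loss with a one-tailed binomial sign test (draws excluded,
α = 0.05), the Friedman rank test in Iman–Davenport F form with critical
value F₀.₉₅(k−1, (k−1)(N−1)), Nemenyi critical differences, and the goal
difference GD = |win| − |loss| with cumulative curves over datasets ordered
by size or attribute count.

## Synthetic data

The generator samples a ground-truth network with exactly the UKDB shape: a
hub set of `k_true` attributes coupled to the class, shared parent of all
other attributes.  Every conditional table is
(1−θ)·uniform + θ·onehot(peak), with peaks drawn per parent configuration
from the seeded RNG, so θ = 0 yields mutual conditional independence and
θ → 1 near-deterministic coupling; the exact joint — hence the Bayes error
— is enumerable for small n and v.  Defaults (n = 5, v = 3, m = 2,
k_true = 1, θ = 0.7, prior 0.655/0.345) emulate a small clinical table
with one dependence hub and mild class imbalance.

`wbc_like(seed)` reproduces the *shape* of the Wisconsin breast cancer
(Original) table — 699 rows, 9 ten-valued attributes, 65.5/34.5 binary
class, 16 missing cells in the Bare Nuclei column, one strongly coupled
attribute pair (1, 2) — not its distribution.  A green test on synthetic
data therefore establishes correctness of the algorithms under a known
generative process (structure recovery, Bayes-consistency, metric
arithmetic), not clinical performance; real-data behavior additionally
depends on attribute interactions the generator deliberately omits
(higher-order dependence, ordinal structure, measurement noise).

## Known limitations

* Attribute and class domains are frozen at training time; unseen test
  values are treated as missing rather than extending the domain.
* Continuous attributes must be discretized (supervised MDL binning or
  equal-frequency); the discretization is learned from training data only.
* The lazy sub-model's posterior is noisier than the training-set model on
  data whose true structure the training-set model already captures — the
  ensemble pays a small premium there and earns it back under model
  misspecification or missing test values.
* No back-off hierarchy for sparse x_p configurations; Laplace smoothing
  alone handles them.
* P(c|x_p) and all CPTs assume moderate k; tables grow as v^k.
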