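# Methods

## Model and assumptions

The pipeline assumes that a population of drug-experienced rats decomposes
into two latent phenotypes — vulnerable (addiction-prone) and resilient —
that are separable in the three-dimensional space of raw instrumental
response counts: motivation under progressive ratio, drug seeking during
signalled unavailability, and responding under punishment. The unsupervised
stage discovers the two groups without thresholds; the supervised stage
turns the discovered partition into a cohort-independent decision function.
Ground truth for validation is deliberately *internal*: the test set's own
cluster labels, so that what is measured is the stability of the partition
under resampling and the transferability of its boundary, not agreement
with the historical criteria (that agreement is checked separately in the
crit-correspondence tables).

## Clustering

* **K-medians** (package implementation): Lloyd alternation under the L1
  (cityblock) distance with coordinate-wise median updates, Forgy
  initialisation (k distinct data points), 25 restarts by default, tol 1e-6
  on the objective, max 300 iterations. Distance ties assign to the lowest
  cluster index; a cluster emptied by an update is re-seeded at the point
  farthest (L1) from its assigned centroid.
* **Global-optimality safeguards.** Lloyd restarts can converge to
  partition-local optima that no restart escapes. After the best restart, a
  greedy polish accepts single-point relocations (and, for k = 2 on cohorts
  of at most 64 points, two-point flips) that strictly lower the objective;
  for k = 2 with n ≤ 12 the bipartition is solved exactly by enumerating
  all 2^(n-1) − 1 splits, which at those sizes is cheaper than restarting.
  Both safeguards keep the objective non-increasing, and the final labels
  are made nearest-centre-consistent by one closing Lloyd pass. The same
  polish is applied to the K-means path (scikit-learn `KMeans` with random
  initialisation).
* **Gaussian mixture**: scikit-learn `GaussianMixture`, full covariances,
  covariance ridge 1e-6, hard labels by maximum posterior responsibility.
* **Standardisation.** Features are z-scored per dimension on training
  statistics before clustering and classification; the statistics are
  stored in the model so test and future animals are transformed
  identically. A constant dimension is centred but left unscaled. A
  no-scaling mode exists for sensitivity checks.
* **Role orientation.** With k = 2, the cluster whose centroid has the
  larger punished-responding coordinate in original units is vulnerable;
  ties fall back to motivation, then seeking; a complete tie is an error,
  never a silent guess.
* **Cluster number.** Silhouette voting scans k = 2–6 (the second-most
  common vote in practice lands in 3–6, so the scan covers it) on each
  resampled set, using the clustering method's own metric (L1 for
  K-medians) by default; the modal best-k across sets wins, ties toward
  smaller k.

## Predictors

Defaults (all overridable per config): KNN with 5 neighbours (odd, no vote
ties); logistic regression with a near-unregularised L2 penalty (C = 1e4;
cohorts are small); RBF-kernel SVM with scale bandwidth whose score is a
logistic (Platt) calibration of the signed margin fitted on training
margins via 3-fold internal cross-validation. The neural network is a plain
feed-forward stack of ELU hidden layers (width 8 by default — inputs are
three-dimensional — depth 5, with 50 and 500 supported), binary
cross-entropy loss, trained full-batch by gradient descent with a
backtracking line search that only accepts non-increasing training loss
(initial step 0.01, halved on rejection, grown 1.2× on acceptance), and
early stopping on a 20% held-out validation fraction with patience 20 and
best-weight restoration. Initial weights are He-scaled (gain 2) for the ELU
nonlinearity. Depth 500 is run as-is: plain 500-layer stacks generally
cannot train from random initialisation without residual connections, and
the implementation runs them to early stopping and reports whatever they
achieve rather than capping the depth.

## Evaluation loop

50 uniform random splits, test fraction 0.33 (n = 88 gives 59/29). Per
split: standardise on training statistics, cluster both halves separately
at k = 2, orient both partitions by the centroid rule, train the predictor
on the training half's roles, predict the test half, tally TV/FR/FV/TR
against the test half's own cluster roles. Per-split seeds are derived by
hashing the split's membership together with the master seed, so summaries
are invariant to the order splits are processed in. Iterations where either
half collapses to a single role, orientation is ambiguous, or training
roles are single-class are excluded and counted, never silently dropped.
"Top decile" is the fraction of iterations with a metric ≥ 0.90 — the top
tenth of the metric's range, the only reading consistent with reporting
values like 58% (a within-sample decile would be 10% by construction).
Precision/recall with zero denominators are flagged undefined and excluded
from that metric's median with counts reported. ROC-AUC uses the
continuous vulnerability score (Mann–Whitney construction, ties ½), not
hard labels. Metric densities are Gaussian KDEs with boundary reflection at
0 and 1 so the curve integrates to one on the unit interval; zero-variance
samples fall back to a fixed bandwidth of 0.01 and are flagged. Curves are
emitted as data, not images.

## Synthetic cohorts

The generator emulates the population structure of outbred rats screened
with the 3-criteria model: ~20% fully vulnerable animals; a bimodal
compulsivity dimension in which the resilient majority draws log-normal
percent resistance to punishment clipped to the 0–30% band (default median
10%, geometric SD 1.6) and the vulnerable minority draws a normal centred
at 92.5% (SD 6, clipped to 0–120%); log-normal motivation and seeking on
both sides with ~3-fold between-role separation by default. Percent
resistance is latent; the emitted feature is the punished response *count*,
resistance × a per-animal log-normal baseline intake (median 100, geometric
SD 1.3, truncated at ±3 geometric SDs to keep counts physiological),
rounded to an integer, because the algorithms consume raw counts.
Intermediate (1–2-criteria-like) animals — 20% by default — draw a random
one or two dimensions from the vulnerable component and the rest from the
resilient one; their pseudo-crit label is the number of vulnerable
dimensions drawn. Within-role dimensions share a weak Gaussian-copula
correlation (0.2) reflecting that the three constructs overlap only
marginally. Log-normals are parameterised by (median, geometric SD) for
interpretability. The `well_separated` scenario (no intermediates, ≥4-fold
separation, tight baselines, resistance bands clipped apart) guarantees
linear separability on the punished count alone and anchors the
planted-truth tests; `paper_like_cocaine` / `paper_like_alcohol` use the
real screens' sizes (88 and 150) with the default overlapping structure.

What passing tests on these cohorts shows — and does not. The generator
plants genuinely two-component structure with known roles, so recovery and
label-transfer results certify the machinery, not the biology: real screens
differ in strain, response modality and housing, their dimensions' true
covariance is unknown, and session-level dynamics (escalation, relapse) are
not simulated. Under the default overlapping conditions an occasional
extreme-group animal (planted 0crit or 3crit) can land across the cluster
boundary, so the synthetic correspondence tables reproduce the zero
off-diagonals typically but not identically in every random cohort —
unlike the deposited empirical tables, where the intersection is absolute.

## Problem sizes

The shipped tests and the acceptance script run the full 50-split loop at
the study's cohort sizes (88 and 150), the silhouette vote over 50 training
sets, exhaustive-bipartition cross-checks at n ≤ 8, and null simulations at
n = 2000; a complete run takes on the order of one to two minutes on a
single CPU.

## Known limitations

* Binary roles only: intermediate animals receive no severity grading.
* A classifier trained on one drug's screen does not transfer to another
  drug; references must be fitted per substance.
* The deposited supplementary tables of the original screens are not
  bundled; the `reproduce-*` commands and the corresponding test run only
  when those files are supplied locally, with an explicit column map.
* Depth-500 networks are supported but rarely trainable (see above); they
  exist to probe depth scaling, not as a recommended configuration.
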