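# Methods

This note records the scientific assumptions, parameter choices and known
limitations behind `targetfish`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Similarity model and the PR-score

Molecules are fingerprinted as sparse sets of hashed circular substructure
identifiers (Morgan environments). The default radius is 2 (ECFP4-
equivalent); fingerprints are kept as feature *sets* rather than folded bit
vectors so the Tanimoto coefficient is exact — folding to 1024/2048 bits is
available (`fingerprints.fold`) for interoperability but plays no part in
scoring. Hydrogens are implicit and stereochemistry is ignored: two
stereoisomers receive identical fingerprints.

The similarity-to-probability transform assumes that the Tanimoto
similarity X of a random compound pair has an exceedance curve of
half-Gaussian shape, P(X > t) = exp(−t²/2h²). The bandwidth **h = 0.125**
(dimensionless, on the Tanimoto scale) is the package default; it was fitted
on a large bioactivity database and can be refitted to any compound
collection with `fit_smoothing_factor`, which minimises the squared error
between the collection's empirical exceedance curve and the model on a
fixed 201-point grid over [0, 1]. A constant or all-zero similarity sample
carries no scale information and is rejected. Parameter recovery is exact
to ±0.01 on 10⁵ sampled similarities (tested for h = 0.125 and 0.2).

The molecule-family score f(x, ω) = (1/n) Σⱼ p(X > t(x, xⱼ)) is an
arithmetic mean, so it is invariant to duplicating members and decreases
monotonically as any member is replaced by a more query-similar one. The
terms "PR-score" and family-level "p-value" refer to the same number;
the code uses `pr_score` throughout. The significance cut-off **α = 0.05**
is an operating point, not a calibrated false-positive rate: no decoy
calibration is performed.

When a query is itself a member of a family, its fingerprint is removed
from the family before scoring (held-out semantics). A family emptied by
this exclusion is omitted from the ranking and reported. Ranking ties are
broken lexicographically by family id, making predictions deterministic.

## Bioactivity rules

One threshold rule per assay type (active side): IC50 ≤ 50 µM, Ki < 20 µM,
Kd ≤ 10 µM, EC50 ≤ 40 µM, ED50 ≤ 10 µM, Potency ≤ 10 µM, Activity ≥ 40%,
Inhibition ≥ 45%. Concentrations are normalised internally to nM; percent
values are compared as-is. Strict/non-strict boundaries follow the table
exactly (a Ki of exactly 20 µM is inactive; an IC50 of exactly 50 µM is
active).

Design choices where the rule table alone does not decide:

* **Explicit labels win.** A curator-assigned active/inactive label
  overrides the numeric rule, since such labels are the evidence the
  thresholds were derived from in the first place.
* **Censored relations are conservative with one documented exception.** A
  bound classifies a record only when it guarantees one side of the rule
  (e.g. "≤ 30 µM" is active for IC50; "≥ 60 µM" is inactive; "< 100 µM" is
  indeterminate). The exception: a "≤" record exactly at a strict
  threshold (Ki "≤ 20 µM") is treated as active although the bound is
  compatible with the inactive boundary point — a deliberate, slightly
  generous reading of an infinitely thin case.
* **`unspecified` relations are treated as equalities**, matching the
  dominant usage in database exports.
* **Any-active membership.** A compound with conflicting records on one
  target (one active, one inactive) belongs to the filtered family:
  membership requires the existence of qualifying activity, not consensus.
* Indeterminate records never contribute to filtered membership but do
  keep a compound in the original family.

## Parameter-free clustering

The clustering takes only a similarity matrix and a seed. Its constants
are declared defaults, exposed in `PFClustConfig`, chosen once and not
tuned per dataset:

* **Threshold candidates by randomization** — 100 rounds; each draws a
  random subset (size uniform in [2, min(n, 20)]) and records its mean
  pairwise similarity; candidate thresholds are the {10, 20, 30, 40, 50,
  60, 70, 75, 80, 85, 90, 95, 99} percentiles of those means. The lower
  percentiles guarantee that a coarse, few-cluster candidate is always on
  the menu. Non-positive candidates are discarded, so a matrix with no
  similarity signal yields only singletons.
* **Agglomerative build per candidate** — seed with the most similar
  unassigned pair (if ≥ threshold), grow by the unassigned item with the
  highest mean similarity to the cluster while that mean stays ≥ the
  threshold; repeat; then merge clusters whose mean cross-similarity still
  reaches the threshold (so a homogeneous block cannot fragment merely
  because growth stopped early); leftovers are singletons.
* **Selection by silhouette** — computed on 1 − similarity distances with
  singletons acting as their own groups for the separation term.
  Candidates are *selected* by the silhouette averaged over **all** items
  (singletons contributing 0): averaging only over clustered items would
  reward clustering the single tightest pair and declaring everything else
  a singleton, which measurably fragments planted scaffold families. The
  *reported* `Clustering.quality` is the conventional mean over clustered
  items. Ties go to fewer clusters, then the higher threshold.
* **No-structure fallback** — if no candidate reaches the conventional
  "substantial structure" silhouette of 0.25 (the Kaufman–Rousseeuw rule
  of thumb), the coarsest candidate (fewest groups) is returned: for data
  without separable structure the honest answer is one undivided cluster,
  not an arbitrary split. A consequence worth knowing: a single
  homogeneous series with mild internal gradients may still come back as
  one or two groups rather than guaranteed-one.

Refinement applies this clustering to each filtered family's Tanimoto
matrix; every cluster and every singleton becomes a refined family
carrying its parent's id, and the union of children always equals the
parent exactly. Singleton refined families are kept because queries are
scored against them (their PR-score is a single p-value).

## Cross-validation and the MCC

"Fivefold Monte Carlo" is implemented as 5 independent random-subsampling
runs, each holding out ⌈0.1·n⌉ members per family — not a 5-fold
partition. Families with fewer than 2 members are never queried (holding
out the only member leaves nothing to score against) and are reported as
skipped.

The confusion bookkeeping, which the MCC needs and which has no single
canonical definition for a ranking task, is: each query issues exactly one
positive — its top-ranked family. A correct top-1 contributes one TP and
one TN per remaining family; a miss contributes one FP (the wrongly
top-ranked family), one FN (the missed parent) and one TN per remaining
family. This spreads each decision over the whole panel and makes MCC
comparable across family definitions with different panel sizes. At
chance-level accuracy this bookkeeping gives MCC ≈ 0 exactly, which the
shuffled-label null model (`shuffle_family_labels`) verifies. On small
panels a *single* shuffle has a null-MCC standard deviation around 0.1, so
null checks average over ~20 independent shuffles.

## Synthetic study libraries

The generator plants each target family as one or more scaffold series: a
ring-system core plus a family-specific tail shared by all members, with an
enumerated small terminal substituent per member. Measured on the default
vocabulary, within-series Tanimoto is ≈ 0.6–0.9 and between-series ≈
0.05–0.3 — strong but not caricatured separation. Activity values are
placed deterministically at threshold × (1 ± noise) (default noise 0.5) on
the intended side of each rule, cycling through all eight assay types and
units (µM and nM), so every generated record also exercises the rule
table. Every fifth planted member receives an additional conflicting
inactive record (exercising any-active membership). Inactive noise members
are drawn from a separate pool of acyclic cores, are added on top of the
planted members at a count making them the configured fraction of total
membership, and alternate between inactive and censored-indeterminate
records; every other noise compound also gets a record against a second
family, emulating cross-family compound sharing. All ground truth is
written to a machine-checkable truth object.

The default study conditions are 3 families × 2 scaffolds × 8 members with
30% inactive noise (69 molecules) — small enough that the full pipeline
runs in seconds, large enough that a 10% holdout is non-trivial. What the
generator does **not** emulate: the heavy-tailed family-size distribution
of real databases, assay noise within a series (values sit exactly at
threshold × (1 ± noise)), tautomers/stereochemistry, and realistic
similarity between unrelated compounds (between-series similarity is lower
and cleaner than in a real collection). Passing tests therefore
demonstrate correctness and the qualitative stage-ordering effect, not
absolute retrieval rates transferable to real data.

## Profiling

A panel is profiled as the matrix of PR-scores against all families
(optionally restricted to rows whose best score reaches α). Compounds are
clustered by structure (Tanimoto matrix) and by activity profile:
Euclidean distances between score columns are mapped to similarities by
s = 1/(1 + d) — monotone, parameter-free, bounded in (0, 1] — and fed to
the same clustering. The choice of this map is a design decision; any
monotone bounded map preserves the clustering's qualitative behaviour but
the exact partition may differ. Cells blanked by self-exclusion or
known-activity exclusion are NaN and are ignored pairwise in the distance
computation.

## Numerical and degenerate-input conventions

* Similarity matrices are validated (symmetry, range, unit diagonal) at
  1e−9 absolute tolerance.
* `gaussian_pvalue` rejects similarities outside [0, 1] and bandwidths
  ≤ 0; at t = 1, h = 0.125 the p-value is e⁻³² ≈ 1.3 × 10⁻¹⁴, far above
  float underflow.
* Two empty fingerprints have no defined Tanimoto (raised as an error);
  an empty fingerprint against a non-empty one scores 0.
* Seeds: every stochastic step (threshold randomization, holdout
  sampling, noise generation) flows from one master seed through
  `numpy.random.SeedSequence`, so whole-pipeline runs are bit-reproducible.

## Known limitations

* The bandwidth default h = 0.125 is appropriate for ECFP4-like sparse
  fingerprints; other descriptors need refitting.
* PR-scores are not multiplicity-corrected: profiling thousands of
  families at α = 0.05 will produce false positives at roughly that rate
  among unrelated families.
* The clustering is O(n²)–O(n³) in family size and is intended for
  families up to a few thousand members, not whole-database clustering in
  one call.
* Alternative descriptor families (MACCS keys, hybrid selections) and
  alternative clustering backends are out of scope by design — the point
  of the clustering stage is parameter-freedom.
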