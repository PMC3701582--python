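"""Monte Carlo cross-validation across the three family definitions.

Holds out 10% of every family's members as queries (5 independent
runs), ranks all families for each query by PR-score, and reports top-1
and top-4 retrieval plus the Matthews Correlation Coefficient.  On a
library with inactive noise members, refinement visibly pays off:
refined >= filtered >= original.
"""

import targetfish as tf

cfg = tf.SynthConfig(n_families=3, scaffolds_per_family=2, members_per_scaffold=8,
                     inactive_fraction=0.3, seed=11)
lib = tf.generate_library(cfg)
fps = tf.compute_fingerprints(lib.molecules)

original = tf.build_original_families(lib.records)
filtered = tf.build_filtered_families(lib.records)
refined = tf.refine_families(filtered, fps, seed=11)

print(f"library: {len(lib.molecules)} molecules "
      f"({sum(i['role'] == 'noise' for i in lib.truth['compounds'].values())} inactive noise)\n")
print(f"{'stage':10s} {'families':>8s} {'top-1':>7s} {'top-4':>7s} {'MCC':>7s}")
for fams in (original, filtered, refined):
    report = tf.monte_carlo_cv(fams, fps, runs=5, fraction=0.1, seed=11)
    print(f"{report.family_stage:10s} {len(fams):8d} {report.top1_rate:7.1%} "
          f"{report.top4_rate:7.1%} {report.mean_mcc:7.3f}")
# Original families carry inactive, structurally unrelated members that
# dilute the score; filtering removes them, and scaffold refinement gives
# each query a structurally coherent parent to hit.
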