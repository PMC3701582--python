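"""Score a query molecule against compound families with the PR-score.

The PR-score of a query against a family is the mean over members of
exp(-t^2 / 2h^2), where t is the query-member Tanimoto similarity and
h = 0.125 the fitted bandwidth.  Low scores mean the query is unlikely
to reach that similarity by chance: the family is a predicted target.
"""

import targetfish as tf

# two small ligand series (e.g. two unrelated targets) plus the query
series_a = [tf.Molecule(f"a{i}", s) for i, s in enumerate(
    ["CCNC(=O)c1ccc2ccccc2c1", "CCCNC(=O)c1ccc2ccccc2c1",
     "CNC(=O)c1ccc2ccccc2c1", "OCCNC(=O)c1ccc2ccccc2c1"])]
series_b = [tf.Molecule(f"b{i}", s) for i, s in enumerate(
    ["CCOC(=O)C1CCNCC1", "CCCOC(=O)C1CCNCC1", "COC(=O)C1CCNCC1"])]
query = tf.Molecule("query", "NCCNC(=O)c1ccc2ccccc2c1")  # a series-a analogue

fps = tf.compute_fingerprints(series_a + series_b + [query])
families = [
    tf.Family("naphthamide-ligands", "filtered", frozenset(m.id for m in series_a)),
    tf.Family("piperidine-esters", "filtered", frozenset(m.id for m in series_b)),
]

for p in tf.predict_targets(query, families, fps, tf.ScoringParams(h=0.125, alpha=0.05)):
    print(f"rank {p.rank}: {p.family_id:20s} pr_score={p.pr_score:.3e} "
          f"significant={p.significant}")
# The naphthamide family scores far below alpha = 0.05 (a confident target
# prediction); the unrelated piperidine-ester family scores near 1.
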