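"""Classify bioactivity records with the per-assay threshold rules.

Builds a handful of measurements against one target and shows how the
rule table (IC50 <= 50 uM, Ki < 20 uM, ..., Inhibition >= 45%) turns
them into active / inactive / indeterminate calls, and how filtered
families keep only the experimentally active compounds.
"""

import targetfish as tf

records = [
    # (compound, target family, type, relation, value, unit)
    tf.ActivityRecord("aspirin-like", "T1", "IC50", "=", 30, "uM"),
    tf.ActivityRecord("weak-binder", "T1", "Ki", "=", 20, "uM"),
    tf.ActivityRecord("nm-potent", "T1", "IC50", "=", 50_000, "nM"),
    tf.ActivityRecord("censored", "T1", "IC50", ">", 10, "uM"),
    tf.ActivityRecord("blocker", "T1", "Inhibition", "=", 45, "percent"),
    tf.ActivityRecord("curated", "T1", "IC50", "=", 1, "nM", explicit_label="inactive"),
]

for r in records:
    label = tf.classify_record(r)
    print(f"{r.compound_id:13s} {r.activity_type:10s} {r.relation}{r.value:g} {r.unit:7s}"
          f" -> {label}")

original = tf.build_original_families(records)
filtered = tf.build_filtered_families(records)
print(f"\noriginal family size: {len(original[0].member_ids)}  "
      f"(every compound with any record)")
print(f"filtered family size: {len(filtered[0].member_ids)}  "
      f"members: {sorted(filtered[0].member_ids)}")
# 'censored' (>10 uM could be above or below 50 uM) and 'curated' (explicit
# inactive label beats its potent numeric value) are excluded; 'weak-binder'
# sits exactly at the strict Ki threshold and is inactive.
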