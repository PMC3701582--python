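import itertools

import pytest

import targetfish as tf
from conftest import record
from targetfish.activity_filter import DEFAULT_RULES, rules_from_dict

# (type, relation, value, unit) -> expected label
SPEC_CASES = [
    ("IC50", "=", 50, "uM", "active"),        # at the threshold, non-strict
    ("Ki", "=", 20, "uM", "inactive"),        # at the threshold, strict
    ("Inhibition", "=", 45, "percent", "active"),
    ("IC50", "=", 50_000, "nM", "active"),    # unit conversion: 50000 nM = 50 uM
    ("IC50", ">", 10, "uM", "indeterminate"),  # bound cannot decide <=50 vs >50
    ("Kd", "=", 10, "uM", "active"),
    ("EC50", "=", 40, "uM", "active"),
    ("ED50", "=", 10, "uM", "active"),
    ("Potency", "=", 10, "uM", "active"),
    ("Activity", "=", 40, "percent", "active"),
]


@pytest.mark.parametrize("atype,relation,value,unit,expected", SPEC_CASES)
def test_rule_table_examples(atype, relation, value, unit, expected):
    assert tf.classify_record(record(atype, relation, value, unit)) == expected


def test_boundary_strictness_all_eight_types():
    """Values a hair across each threshold flip exactly per the rule signs."""
    for atype, rule in DEFAULT_RULES.items():
        t = rule.threshold_value
        unit = "percent" if rule.threshold_unit == "percent" else "uM"
        eps = t * 1e-6
        below = tf.classify_record(record(atype, "=", t - eps, unit))
        at = tf.classify_record(record(atype, "=", t, unit))
        above = tf.classify_record(record(atype, "=", t + eps, unit))
        if rule.direction == "at_most":
            assert (below, at, above) == ("active", "active", "inactive")
        elif rule.direction == "less_than":
            assert (below, at, above) == ("active", "inactive", "inactive")
        else:  # at_least
            assert (below, at, above) == ("inactive", "active", "active")


def test_classification_total_over_type_relation_unit_grid():
    """Every convertible (type, relation, unit, value) combination classifies."""
    for atype, rule in DEFAULT_RULES.items():
        units = ("percent",) if rule.threshold_unit == "percent" else ("nM", "uM", "mM", "M")
        values = (0.0, rule.threshold_value * 0.1, rule.threshold_value, rule.threshold_value * 10)
        for relation, unit, value in itertools.product(
            ("=", "<", "<=", ">", ">=", "unspecified"), units, values
        ):
            label = tf.classify_record(record(atype, relation, value, unit))
            assert label in ("active", "inactive", "indeterminate")


def test_censored_relations_never_promote_on_ambiguity():
    # "<= 30 uM" guarantees IC50 <= 50 uM -> active
    assert tf.classify_record(record("IC50", "<=", 30, "uM")) == "active"
    # ">= 60 uM" guarantees the inactive side
    assert tf.classify_record(record("IC50", ">=", 60, "uM")) == "inactive"
    # "< 100 uM" is compatible with both sides
    assert tf.classify_record(record("IC50", "<", 100, "uM")) == "indeterminate"
    # percent rules mirrored: "> 50%" guarantees Inhibition >= 45%
    assert tf.classify_record(record("Inhibition", ">", 50, "percent")) == "active"
    assert tf.classify_record(record("Inhibition", "<", 40, "percent")) == "inactive"
    assert tf.classify_record(record("Inhibition", ">", 30, "percent")) == "indeterminate"


def test_explicit_label_overrides_numeric_rule():
    assert tf.classify_record(record("IC50", "=", 1, "nM", label="inactive")) == "inactive"
    assert tf.classify_record(record("IC50", "=", 900, "uM", label="active")) == "active"


def test_percent_record_with_concentration_unit_is_unrepresentable():
    with pytest.raises(ValueError):
        record("Activity", "=", 50, "uM")


def test_original_families_keep_all_associated_compounds():
    records = [
        record("IC50", "=", 1, "uM", compound="a", family="F1"),     # active
        record("IC50", "=", 500, "uM", compound="b", family="F1"),   # inactive
        record("IC50", ">", 10, "uM", compound="c", family="F1"),    # indeterminate
    ]
    fams = tf.build_original_families(records)
    assert len(fams) == 1
    assert fams[0].member_ids == {"a", "b", "c"} and fams[0].stage == "original"


def test_compound_on_two_targets_is_member_of_both():
    records = [
        record(compound="a", family="F1", value=1),
        record(compound="a", family="F2", value=1),
    ]
    fams = tf.build_original_families(records)
    assert all("a" in f.member_ids for f in fams) and len(fams) == 2


def test_filtered_families_keep_only_active_compounds():
    records = [
        record("IC50", "=", 1, "uM", compound="a", family="F1"),
        record("IC50", "=", 500, "uM", compound="b", family="F1"),
        record("IC50", ">", 10, "uM", compound="c", family="F1"),
    ]
    fams = tf.build_filtered_families(records)
    assert len(fams) == 1 and fams[0].member_ids == {"a"} and fams[0].stage == "filtered"


def test_any_active_rule_with_conflicting_records():
    records = [
        record("IC50", "=", 1, "uM", compound="a", family="F1"),   # active by IC50
        record("Ki", "=", 900, "uM", compound="a", family="F1"),   # inactive by Ki
    ]
    fams = tf.build_filtered_families(records)
    assert fams[0].member_ids == {"a"}


def test_all_inactive_target_yields_no_filtered_family():
    records = [record("IC50", "=", 500, "uM", compound="a", family="F1")]
    assert tf.build_filtered_families(records) == []


def test_empty_record_set_rejected():
    with pytest.raises(ValueError):
        tf.build_original_families([])
    with pytest.raises(ValueError):
        tf.build_filtered_families([])


def test_filtered_subset_of_original(noisy_library):
    lib, _ = noisy_library
    orig = {f.family_id: f.member_ids for f in tf.build_original_families(lib.records)}
    for fam in tf.build_filtered_families(lib.records):
        assert fam.member_ids <= orig[fam.family_id]


def test_rule_overrides_from_config():
    rules = rules_from_dict({"IC50": {"direction": "at_most", "threshold_value": 1,
                                      "threshold_unit": "uM"}})
    assert tf.classify_record(record("IC50", "=", 5, "uM"), rules) == "inactive"
    assert rules["Ki"] == DEFAULT_RULES["Ki"]
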