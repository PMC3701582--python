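"""Bioactivity rule table and family construction.

A compound's membership in a *filtered* family requires at least one
experimental record that qualifies as active under a per-assay-type
threshold rule:

=========== =========== ==========
type        active      inactive
=========== =========== ==========
IC50        <= 50 uM    > 50 uM
Ki          <  20 uM    >= 20 uM
Kd          <= 10 uM    > 10 uM
EC50        <= 40 uM    > 40 uM
ED50        <= 10 uM    > 10 uM
Potency     <= 10 uM    > 10 uM
Activity    >= 40 %     < 40 %
Inhibition  >= 45 %     < 45 %
=========== =========== ==========

Curator-assigned explicit active/inactive labels take precedence over
the numeric rule.  Censored relations (<, <=, >, >=) are honoured
conservatively: a record is promoted to active only when the stated
bound guarantees the active side of the rule, and demoted to inactive
only when it guarantees the inactive side; everything else is
*indeterminate* and never contributes to filtered membership.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from .models import ACTIVITY_TYPES, ActivityRecord, Family

#: Conversion factors from each concentration unit to nM.
_TO_NM = {"nM": 1.0, "uM": 1e3, "mM": 1e6, "M": 1e9}


@dataclass(frozen=True)
class ActivityRule:
    """Threshold rule for one assay type.

    ``direction`` gives the active-side comparison against the threshold:
    ``at_most`` (v <= T), ``less_than`` (v < T) or ``at_least`` (v >= T).
    """

    activity_type: str
    direction: str  # at_most | less_than | at_least
    threshold_value: float
    threshold_unit: str  # uM | percent

    def __post_init__(self) -> None:
        if self.direction not in ("at_most", "less_than", "at_least"):
            raise ValueError(f"unknown rule direction {self.direction!r}")
        if self.threshold_unit not in ("uM", "percent"):
            raise ValueError(f"rule threshold unit must be uM or percent")


DEFAULT_RULES: dict[str, ActivityRule] = {
    "IC50": ActivityRule("IC50", "at_most", 50.0, "uM"),
    "Ki": ActivityRule("Ki", "less_than", 20.0, "uM"),
    "Kd": ActivityRule("Kd", "at_most", 10.0, "uM"),
    "EC50": ActivityRule("EC50", "at_most", 40.0, "uM"),
    "ED50": ActivityRule("ED50", "at_most", 10.0, "uM"),
    "Potency": ActivityRule("Potency", "at_most", 10.0, "uM"),
    "Activity": ActivityRule("Activity", "at_least", 40.0, "percent"),
    "Inhibition": ActivityRule("Inhibition", "at_least", 45.0, "percent"),
}

assert set(DEFAULT_RULES) == set(ACTIVITY_TYPES)


def _normalise(record: ActivityRecord, rule: ActivityRule) -> tuple[float, float]:
    """Return (value, threshold) on a common scale (nM or percent)."""
    if rule.threshold_unit == "percent":
        if record.unit != "percent":
            raise ValueError(
                f"cannot convert unit {record.unit!r} for percent rule {rule.activity_type}"
            )
        return record.value, rule.threshold_value
    if record.unit not in _TO_NM:
        raise ValueError(f"non-convertible unit {record.unit!r} for {rule.activity_type}")
    return record.value * _TO_NM[record.unit], rule.threshold_value * _TO_NM["uM"]


def classify_record(
    record: ActivityRecord, rules: Mapping[str, ActivityRule] = DEFAULT_RULES
) -> str:
    """Classify one record as ``active``, ``inactive`` or ``indeterminate``.

    An explicit curator label wins over the numeric rule.  The relation
    qualifier is interpreted conservatively; ``unspecified`` is treated
    as an equality, matching the dominant usage in database exports.
    """
    if record.explicit_label is not None:
        return record.explicit_label
    rule = rules[record.activity_type]
    value, threshold = _normalise(record, rule)
    relation = "=" if record.relation == "unspecified" else record.relation

    if rule.direction in ("at_most", "less_than"):
        # Active side is below the threshold (concentration rules).
        if relation == "=":
            if rule.direction == "at_most":
                return "active" if value <= threshold else "inactive"
            return "active" if value < threshold else "inactive"
        if relation in ("<", "<="):
            return "active" if value <= threshold else "indeterminate"
        # relation in (">", ">=")
        return "inactive" if value >= threshold else "indeterminate"

    # at_least: active side is above the threshold (percent rules).
    if relation == "=":
        return "active" if value >= threshold else "inactive"
    if relation in (">", ">="):
        return "active" if value >= threshold else "indeterminate"
    return "inactive" if value <= threshold else "indeterminate"


def _target_names(records: Iterable[ActivityRecord]) -> dict[str, str]:
    names: dict[str, str] = {}
    for r in records:
        if r.family_id not in names and r.target_name:
            names[r.family_id] = r.target_name
    return names


def build_original_families(records: list[ActivityRecord]) -> list[Family]:
    """One family per target containing every compound with any record.

    This mirrors the raw database association semantics: a compound is
    associated with a target whenever an experimental record exists,
    even if that record shows inactivity.
    """
    if not records:
        raise ValueError("no activity records supplied")
    members: dict[str, set[str]] = {}
    for r in records:
        members.setdefault(r.family_id, set()).add(r.compound_id)
    names = _target_names(records)
    return [
        Family(
            family_id=fid,
            stage="original",
            member_ids=frozenset(ids),
            target_name=names.get(fid),
        )
        for fid, ids in sorted(members.items())
    ]


def build_filtered_families(
    records: list[ActivityRecord], rules: Mapping[str, ActivityRule] = DEFAULT_RULES
) -> list[Family]:
    """One family per target containing the compounds with >= 1 active record.

    A compound with conflicting records on the same target (one active,
    one inactive) is included: membership requires the *existence* of
    qualifying experimental activity, not a consensus.  Targets left
    with zero active compounds yield no filtered family.
    """
    if not records:
        raise ValueError("no activity records supplied")
    members: dict[str, set[str]] = {}
    for r in records:
        if classify_record(r, rules) == "active":
            members.setdefault(r.family_id, set()).add(r.compound_id)
    names = _target_names(records)
    return [
        Family(
            family_id=fid,
            stage="filtered",
            member_ids=frozenset(ids),
            target_name=names.get(fid),
        )
        for fid, ids in sorted(members.items())
        if ids
    ]


def rules_from_dict(spec: Mapping[str, Mapping]) -> dict[str, ActivityRule]:
    """Build a rule table from a config mapping (e.g. parsed YAML).

    Expected shape: ``{type: {direction, threshold_value, threshold_unit}}``.
    Types not mentioned keep their defaults.
    """
    rules = dict(DEFAULT_RULES)
    for atype, d in spec.items():
        if atype not in ACTIVITY_TYPES:
            raise ValueError(f"unknown activity type in rule config: {atype!r}")
        rules[atype] = ActivityRule(
            activity_type=atype,
            direction=d["direction"],
            threshold_value=float(d["threshold_value"]),
            threshold_unit=d["threshold_unit"],
        )
    return rules
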