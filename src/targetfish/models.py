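"""Core domain types shared across the pipeline.

The pipeline moves compounds through three family stages:

``original``
    every compound with any bioactivity record against a target,
    active or not (the raw database association semantics);
``filtered``
    only compounds with at least one record classified *active*
    under the bioactivity rule table;
``refined``
    scaffold-coherent subsets of a filtered family found by
    parameter-free structural clustering.

A query molecule is scored against a family with the
Parzen-Rosenblatt score (PR-score): the mean, over family members,
of the Gaussian-transformed p-value of the query-member Tanimoto
similarity.  Lower PR-scores indicate stronger association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The eight assay categories covered by the bioactivity rule table.
ACTIVITY_TYPES = (
    "IC50",
    "Ki",
    "Kd",
    "EC50",
    "ED50",
    "Potency",
    "Activity",
    "Inhibition",
)

#: Relation qualifiers accepted on activity values.
RELATIONS = ("=", "<", "<=", ">", ">=", "unspecified")

#: Concentration units convertible to nM, plus percent for
#: Activity/Inhibition records.
UNITS = ("nM", "uM", "mM", "M", "percent")

FAMILY_STAGES = ("original", "filtered", "refined")


@dataclass(frozen=True)
class Molecule:
    """A compound: an identifier plus its canonical SMILES."""

    id: str
    smiles: str
    name: str | None = None
    tags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ActivityRecord:
    """One experimental measurement linking a compound to a target family.

    ``value``/``unit`` are stored exactly as loaded; unit normalisation
    happens only inside the rule classifier.  ``explicit_label`` carries a
    curator-assigned active/inactive call, which takes precedence over the
    numeric rules.
    """

    compound_id: str
    family_id: str
    activity_type: str
    relation: str
    value: float
    unit: str
    target_name: str | None = None
    explicit_label: str | None = None

    def __post_init__(self) -> None:
        if self.activity_type not in ACTIVITY_TYPES:
            raise ValueError(f"unknown activity_type {self.activity_type!r}")
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"value must be a non-negative number, got {self.value}")
        if self.activity_type in ("Activity", "Inhibition"):
            if self.unit != "percent":
                raise ValueError(
                    f"{self.activity_type} records carry percent units, got {self.unit!r}"
                )
        elif self.unit == "percent":
            raise ValueError(
                f"{self.activity_type} records carry concentration units, got 'percent'"
            )
        if self.explicit_label is not None and self.explicit_label not in (
            "active",
            "inactive",
        ):
            raise ValueError(f"explicit_label must be active/inactive, got {self.explicit_label!r}")


@dataclass(frozen=True)
class Family:
    """A named set of compound ids at one stage of the curation pipeline."""

    family_id: str
    stage: str
    member_ids: frozenset[str]
    target_name: str | None = None
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in FAMILY_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.member_ids:
            raise ValueError(f"family {self.family_id!r} has no members")
        if self.stage == "refined" and self.parent_id is None:
            raise ValueError(f"refined family {self.family_id!r} must name its parent")
        if self.stage != "refined" and self.parent_id is not None:
            raise ValueError(f"{self.stage} family {self.family_id!r} cannot have a parent")

    @property
    def root_id(self) -> str:
        """Identifier of the target-level (filtered/original) family."""
        return self.parent_id if self.parent_id is not None else self.family_id


@dataclass(frozen=True)
class Fingerprint:
    """Sparse circular-substructure fingerprint of one compound.

    ``features`` holds the hashed atom-environment identifiers present in
    the molecule; Tanimoto similarity operates on these sets directly, so
    no folding collisions are introduced.
    """

    compound_id: str
    features: frozenset[int]
    radius: int


@dataclass
class SimilarityMatrix:
    """All-against-all Tanimoto similarities for an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")

    def validate(self, atol: float = 1e-9) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("similarity matrix is not symmetric")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("similarity values outside [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("similarity matrix diagonal is not 1")


@dataclass
class Clustering:
    """A partition into clusters (size >= 2) plus singletons.

    ``quality`` is the mean silhouette of the items inside clusters,
    computed on 1 - similarity distances.
    """

    clusters: list[frozenset[str]]
    singletons: frozenset[str]
    quality: float

    def all_ids(self) -> frozenset[str]:
        out: set[str] = set(self.singletons)
        for c in self.clusters:
            out.update(c)
        return frozenset(out)

    def labels(self) -> dict[str, int]:
        """Integer label per id; singletons get unique labels after clusters."""
        lab: dict[str, int] = {}
        for k, c in enumerate(self.clusters):
            for i in c:
                lab[i] = k
        for j, i in enumerate(sorted(self.singletons)):
            lab[i] = len(self.clusters) + j
        return lab


@dataclass(frozen=True)
class ScoringParams:
    """Knobs of the PR scoring step.

    h : float
        Bandwidth of the Gaussian similarity-to-p-value transform
        (dimensionless, on the Tanimoto scale). Default 0.125.
    alpha : float
        Significance cut-off on PR-scores. Default 0.05.
    """

    h: float = 0.125
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("bandwidth h must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class Prediction:
    """One (query, family) association with its PR-score and rank."""

    query_id: str
    family_id: str
    pr_score: float
    rank: int
    significant: bool
    known_activity: str = "untested"
    target_name: str | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )


@dataclass
class RunResult:
    """Retrieval statistics of one cross-validation run."""

    queries: int
    top1_hits: int
    top4_hits: int
    counts: ConfusionCounts
    mcc: float
    skipped_families: list[str] = field(default_factory=list)


@dataclass
class CVReport:
    """Monte Carlo cross-validation report for one family stage."""

    family_stage: str
    runs: list[RunResult]

    @property
    def top1_rate(self) -> float:
        q = sum(r.queries for r in self.runs)
        return sum(r.top1_hits for r in self.runs) / q if q else float("nan")

    @property
    def top4_rate(self) -> float:
        q = sum(r.queries for r in self.runs)
        return sum(r.top4_hits for r in self.runs) / q if q else float("nan")

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([r.mcc for r in self.runs])) if self.runs else float("nan")

    def to_dict(self) -> dict:
        return {
            "family_stage": self.family_stage,
            "aggregate": {
                "top1_rate": self.top1_rate,
                "top4_rate": self.top4_rate,
                "mean_mcc": self.mean_mcc,
            },
            "runs": [
                {
                    "queries": r.queries,
                    "top1_hits": r.top1_hits,
                    "top4_hits": r.top4_hits,
                    "counts": {
                        "TP": r.counts.TP,
                        "FP": r.counts.FP,
                        "TN": r.counts.TN,
                        "FN": r.counts.FN,
                    },
                    "mcc": r.mcc,
                    "skipped_families": r.skipped_families,
                }
                for r in self.runs
            ],
        }


@dataclass
class ProfileMatrix:
    """PR-scores of a compound panel (columns) against families (rows)."""

    family_ids: list[str]
    compound_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.family_ids), len(self.compound_ids)):
            raise ValueError("score matrix shape inconsistent with id lists")
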