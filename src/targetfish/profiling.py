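"""Panel profiling: PR-score matrices and dual clustering of a compound set.

A compound panel (for instance one prohibited-list class) is profiled
two ways:

* *by structure* — parameter-free clustering of the panel's Tanimoto
  similarity matrix;
* *by predicted activity* — each compound's column of PR-scores against
  the family panel is treated as a position vector; pairwise Euclidean
  distances between columns are mapped to similarities and clustered
  with the same algorithm.

Compounds that are structurally distinct may still share a predicted
target profile (and vice versa); the co-membership contingency table
makes that comparison explicit.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import pfclust
from .fingerprints import similarity_matrix_from_fps
from .models import (
    ActivityRecord,
    Clustering,
    Family,
    Fingerprint,
    Molecule,
    ProfileMatrix,
    ScoringParams,
    SimilarityMatrix,
)
from .scoring import known_activity_labels, pr_score


def profile_matrix(
    compounds: Sequence[Molecule],
    families: Sequence[Family],
    fps: Mapping[str, Fingerprint],
    params: ScoringParams = ScoringParams(),
    exclude_self: bool = True,
    exclude_known: bool = False,
    activities: Iterable[ActivityRecord] | None = None,
    significant_only: bool = False,
) -> ProfileMatrix:
    """PR-scores of every panel compound against every family.

    ``exclude_self`` removes a compound's own fingerprint from a family
    it belongs to before scoring; ``exclude_known`` additionally blanks
    (sets to NaN) cells where the compound has a known active record on
    the family's target, the protocol used when profiling compounds whose
    activities the database already contains.  With ``significant_only``
    the matrix keeps only rows whose best (minimum) score reaches the
    significance cut-off.
    """
    if not compounds:
        raise ValueError("empty compound panel")
    if not families:
        raise ValueError("empty family set")
    known = known_activity_labels(activities) if exclude_known else {}
    fam_list = list(families)
    comp_list = list(compounds)
    scores = np.full((len(fam_list), len(comp_list)), np.nan)
    for i, fam in enumerate(fam_list):
        for j, comp in enumerate(comp_list):
            members = fam.member_ids - {comp.id} if exclude_self else fam.member_ids
            if not members:
                continue  # emptied by self-exclusion; cell stays NaN
            if exclude_known and known.get((comp.id, fam.root_id)) == "active":
                continue
            scores[i, j] = pr_score(fps[comp.id], (fps[m] for m in sorted(members)), params)

    mat = ProfileMatrix(
        family_ids=[f.family_id for f in fam_list],
        compound_ids=[c.id for c in comp_list],
        scores=scores,
    )
    if significant_only:
        keep = np.nanmin(mat.scores, axis=1) <= params.alpha
        mat = ProfileMatrix(
            family_ids=[fid for fid, k in zip(mat.family_ids, keep) if k],
            compound_ids=mat.compound_ids,
            scores=mat.scores[keep],
        )
    return mat


def activity_similarity(profile: ProfileMatrix) -> SimilarityMatrix:
    """Similarities between compounds' PR-score columns.

    Euclidean distance ``d`` between columns is mapped to ``1 / (1 + d)``:
    monotone, parameter-free and bounded in (0, 1].  NaN cells (untestable
    pairs) are ignored pairwise.
    """
    n = len(profile.compound_ids)
    sims = np.ones((n, n))
    cols = profile.scores
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(np.isnan(cols[:, i]) | np.isnan(cols[:, j]))
            d = float(np.linalg.norm(cols[both, i] - cols[both, j])) if both.any() else 0.0
            sims[i, j] = sims[j, i] = 1.0 / (1.0 + d)
    return SimilarityMatrix(ids=list(profile.compound_ids), values=sims)


def activity_cluster(
    profile: ProfileMatrix,
    seed: int,
    config: pfclust.PFClustConfig = pfclust.DEFAULT_CONFIG,
) -> Clustering:
    """Cluster panel compounds by their predicted-activity profiles."""
    return pfclust.cluster(activity_similarity(profile), seed=seed, config=config)


def structure_cluster(
    compounds: Sequence[Molecule],
    fps: Mapping[str, Fingerprint],
    seed: int,
    config: pfclust.PFClustConfig = pfclust.DEFAULT_CONFIG,
) -> Clustering:
    """Cluster panel compounds by Tanimoto structural similarity."""
    if not compounds:
        raise ValueError("empty compound panel")
    sim = similarity_matrix_from_fps([fps[c.id] for c in compounds])
    return pfclust.cluster(sim, seed=seed, config=config)


def co_membership_table(structural: Clustering, activity: Clustering) -> pd.DataFrame:
    """Contingency table of items across the two clusterings.

    Rows are structural groups, columns activity groups; singletons are
    pooled under a ``singleton`` label on each axis.  The table is exactly
    reconstructible from the two Clustering objects and lets one read off
    where structure- and activity-based groupings agree or split.
    """
    if structural.all_ids() != activity.all_ids():
        raise ValueError("clusterings cover different item sets")

    def group_of(c: Clustering) -> dict[str, str]:
        g: dict[str, str] = {}
        for k, cl in enumerate(c.clusters):
            for i in cl:
                g[i] = f"C{k + 1}"
        for i in c.singletons:
            g[i] = "singleton"
        return g

    gs, ga = group_of(structural), group_of(activity)
    ids = sorted(structural.all_ids())
    df = pd.DataFrame({"structure": [gs[i] for i in ids], "activity": [ga[i] for i in ids]})
    return pd.crosstab(df["structure"], df["activity"])
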