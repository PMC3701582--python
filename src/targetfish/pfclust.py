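"""Parameter-free clustering of a similarity matrix.

The algorithm picks its own similarity threshold, so the user supplies
neither a cluster count nor a cut-off:

1. *Threshold candidates by randomization.*  Random subsets of the
   items are drawn repeatedly and the mean pairwise similarity of each
   subset recorded; fixed percentiles of that empirical distribution
   become the candidate thresholds.  Non-positive candidates are
   discarded (a matrix with no similarity signal yields no threshold
   and therefore only singletons).
2. *Agglomerative build per candidate.*  Seed a cluster with the most
   similar unassigned pair (if at least as similar as the threshold),
   then repeatedly add the unassigned item with the highest mean
   similarity to the cluster while that mean stays above the
   threshold.  Repeat until no pair qualifies; leftover items are
   singletons.  Clusters whose mean cross-similarity still reaches the
   threshold are merged, so a homogeneous block cannot fragment merely
   because growth stopped early.
3. *Selection by silhouette.*  Each candidate partition is scored by
   the mean silhouette (on 1 - similarity distances) of the items
   inside clusters of size >= 2, with singletons acting as their own
   groups for the separation term.  The best-scoring partition wins.
   When no candidate reaches the conventional "substantial structure"
   silhouette of 0.25, the coarsest candidate (fewest groups) is
   returned instead: for data without separable structure the honest
   answer is one undivided cluster rather than an arbitrary split.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

from .fingerprints import similarity_matrix_from_fps
from .models import Clustering, Family, Fingerprint, SimilarityMatrix

_STRUCTURE_FLOOR = 0.25  # Kaufman-Rousseeuw: silhouette below this = no substantial structure


@dataclass(frozen=True)
class PFClustConfig:
    """Constants of the randomization scheme (all defaults are declared, not fitted)."""

    n_rounds: int = 100
    max_subset: int = 20
    percentiles: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 75, 80, 85, 90, 95, 99)
    structure_floor: float = _STRUCTURE_FLOOR


DEFAULT_CONFIG = PFClustConfig()


def _candidate_thresholds(
    values: np.ndarray, rng: np.random.Generator, config: PFClustConfig
) -> np.ndarray:
    n = values.shape[0]
    means = np.empty(config.n_rounds)
    hi = min(n, config.max_subset)
    for r in range(config.n_rounds):
        size = int(rng.integers(2, hi + 1)) if hi > 2 else 2
        idx = rng.choice(n, size=size, replace=False)
        sub = values[np.ix_(idx, idx)]
        means[r] = sub[np.triu_indices(size, k=1)].mean()
    cands = np.unique(np.percentile(means, config.percentiles))
    return cands[cands > 0]


def _build_partition(values: np.ndarray, threshold: float) -> list[list[int]]:
    """Agglomerative clusters at one threshold; items not placed are singletons."""
    n = values.shape[0]
    unassigned = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    masked = values.copy()
    np.fill_diagonal(masked, -1.0)

    while unassigned.sum() >= 2:
        idx = np.flatnonzero(unassigned)
        sub = masked[np.ix_(idx, idx)]
        flat = int(np.argmax(sub))
        i, j = divmod(flat, len(idx))
        if sub[i, j] < threshold:
            break
        members = [int(idx[i]), int(idx[j])]
        unassigned[members] = False
        # running sum of similarity to current members, for mean-linkage growth
        simsum = values[:, members].sum(axis=1)
        while unassigned.any():
            cand = np.flatnonzero(unassigned)
            means = simsum[cand] / len(members)
            k = int(np.argmax(means))
            if means[k] < threshold:
                break
            new = int(cand[k])
            members.append(new)
            unassigned[new] = False
            simsum += values[:, new]
        clusters.append(members)

    # merge pass: clusters whose mean cross-similarity reaches the threshold
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        best: tuple[float, int, int] | None = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                cross = values[np.ix_(clusters[a], clusters[b])].mean()
                if cross >= threshold and (best is None or cross > best[0]):
                    best = (cross, a, b)
        if best is not None:
            _, a, b = best
            clusters[a] = clusters[a] + clusters[b]
            del clusters[b]
            merged = True
    return clusters


def _silhouettes(values: np.ndarray, clusters: list[list[int]]) -> tuple[float, float]:
    """Silhouette summaries of a partition: (clustered-item mean, all-item mean).

    Singletons act as their own groups for the separation term; they
    contribute a silhouette of 0 to the all-item mean.  Both summaries
    are 0.0 by convention when no item is clustered or a single cluster
    covers everything (no second group to separate from).
    """
    n = values.shape[0]
    if not clusters:
        return 0.0, 0.0
    dist = 1.0 - values
    in_cluster = np.zeros(n, dtype=int) - 1
    for k, c in enumerate(clusters):
        for i in c:
            in_cluster[i] = k
    singles = [[i] for i in np.flatnonzero(in_cluster < 0)]
    groups = [list(c) for c in clusters] + singles
    if len(groups) < 2:
        return 0.0, 0.0
    scores = []
    for k, c in enumerate(clusters):
        for i in c:
            a = dist[i, c].sum() / (len(c) - 1)
            b = min(
                dist[i, g].mean() for gk, g in enumerate(groups) if g is not groups[k]
            )
            m = max(a, b)
            scores.append((b - a) / m if m > 0 else 0.0)
    total = float(np.sum(scores))
    return total / len(scores), total / n


def cluster(
    sim: SimilarityMatrix, seed: int, config: PFClustConfig = DEFAULT_CONFIG
) -> Clustering:
    """Partition the items of a similarity matrix without free parameters.

    Deterministic for a fixed seed.  Raises on a non-symmetric or
    out-of-range matrix.
    """
    sim.validate()
    n = len(sim.ids)
    if n == 1:
        return Clustering(clusters=[], singletons=frozenset(sim.ids), quality=0.0)

    rng = np.random.default_rng(seed)
    thresholds = _candidate_thresholds(sim.values, rng, config)
    if thresholds.size == 0:
        return Clustering(clusters=[], singletons=frozenset(sim.ids), quality=0.0)

    # candidates scored by the all-item silhouette mean: a partition must
    # explain the whole matrix, not just cherry-pick its tightest pair
    candidates: list[tuple[float, list[list[int]], float]] = []  # (sel_score, clusters, thr)
    for thr in thresholds:
        parts = _build_partition(sim.values, float(thr))
        _, sel = _silhouettes(sim.values, parts)
        candidates.append((sel, parts, float(thr)))

    best_q = max(q for q, _, _ in candidates)
    if best_q >= config.structure_floor:
        # best silhouette; ties toward fewer clusters, then the higher threshold
        chosen = min(
            (c for c in candidates if c[0] == best_q),
            key=lambda c: (len(c[1]), -c[2]),
        )
    else:
        # no substantial structure: the coarsest partition (fewest groups)
        def n_groups(c):
            clustered = sum(len(p) for p in c[1])
            return len(c[1]) + (n - clustered)

        chosen = min(candidates, key=lambda c: (n_groups(c), -c[2]))

    _, parts, _ = chosen
    clustered_ids = [frozenset(sim.ids[i] for i in p) for p in parts]
    placed = {i for p in parts for i in p}
    singles = frozenset(sim.ids[i] for i in range(n) if i not in placed)
    quality, _ = _silhouettes(sim.values, parts)
    return Clustering(clusters=clustered_ids, singletons=singles, quality=quality)


def refine_families(
    filtered: list[Family],
    fps: Mapping[str, Fingerprint],
    seed: int,
    config: PFClustConfig = DEFAULT_CONFIG,
) -> list[Family]:
    """Split each filtered family into scaffold-coherent refined families.

    Every structural cluster and every singleton becomes its own refined
    family carrying ``parent_id``; the union of the refined members per
    parent equals the parent's membership exactly.
    """
    out: list[Family] = []
    for fam_idx, fam in enumerate(sorted(filtered, key=lambda f: f.family_id)):
        members = sorted(fam.member_ids)
        missing = [m for m in members if m not in fps]
        if missing:
            raise ValueError(f"family {fam.family_id!r}: no fingerprint for {missing}")
        if len(members) == 1:
            groups: list[frozenset[str]] = [frozenset(members)]
        else:
            sim = similarity_matrix_from_fps([fps[m] for m in members])
            fam_seed = int(np.random.SeedSequence([seed, fam_idx]).generate_state(1)[0] % (2**31))
            result = cluster(sim, seed=fam_seed, config=config)
            groups = sorted(result.clusters, key=lambda g: sorted(g)) + [
                frozenset([s]) for s in sorted(result.singletons)
            ]
        for k, g in enumerate(groups, start=1):
            out.append(
                Family(
                    family_id=f"{fam.family_id}.r{k}",
                    stage="refined",
                    member_ids=g,
                    target_name=fam.target_name,
                    parent_id=fam.family_id,
                )
            )
    return out
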