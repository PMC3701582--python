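"""Monte Carlo cross-validation of family retrieval.

Each run holds out 10% (configurable) of every family's members as
queries, removes them from the training membership, and ranks all
families for each query by PR-score.  A query whose parent family
ranks first is a top-1 hit; within the first four ranks, a top-4 hit.

Confusion-matrix accounting (for the Matthews Correlation Coefficient):
every query issues exactly one positive prediction — its top-ranked
family.  If that is the parent, the query contributes one TP and one TN
for every other family; otherwise one FP (the wrongly ranked family),
one FN (the missed parent), and one TN per remaining family.  This
spreads each query's decision over the full family panel, so MCC is
comparable across family definitions with different panel sizes.
"""

from __future__ import annotations

import math
from collections.abc import Mapping

import numpy as np

from .models import ConfusionCounts, CVReport, Family, Fingerprint, RunResult, ScoringParams
from .scoring import pr_score


def shuffle_family_labels(families: list[Family], seed: int = 0) -> list[Family]:
    """Null model: permute compound->family assignment, keeping family sizes.

    Destroys the association between structure and family label while
    preserving the panel's shape; retrieval on shuffled families should
    show chance-level top-1 rates and an MCC near zero.
    """
    rng = np.random.default_rng(seed)
    fams = sorted(families, key=lambda f: f.family_id)
    members = sorted({m for f in fams for m in f.member_ids})
    pool = [members[i] for i in rng.permutation(len(members))]
    out: list[Family] = []
    pos = 0
    for f in fams:
        take = len(f.member_ids)
        if pos + take > len(pool):  # compounds shared between families: reuse the pool
            pool = pool + [members[i] for i in rng.permutation(len(members))]
        out.append(
            Family(
                family_id=f.family_id,
                stage=f.stage,
                member_ids=frozenset(pool[pos : pos + take]),
                target_name=f.target_name,
                parent_id=f.parent_id,
            )
        )
        pos += take
    return out


def mcc(counts: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    with the standard convention of 0 when any denominator factor is 0.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if tp + fp + tn + fn == 0:
        raise ValueError("all confusion counts are zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _rank_of_parent(
    qfp: Fingerprint,
    parent_id: str,
    memberships: dict[str, frozenset[str]],
    fps: Mapping[str, Fingerprint],
    params: ScoringParams,
) -> tuple[int, str]:
    """Rank (1-based) of the parent family for one query, plus the top family."""
    qid = qfp.compound_id
    scored: list[tuple[float, str]] = []
    for fid, members in memberships.items():
        usable = members - {qid}
        if not usable:
            continue
        score = pr_score(qfp, (fps[m] for m in sorted(usable)), params)
        scored.append((score, fid))
    scored.sort(key=lambda s: (s[0], s[1]))
    ranked = [fid for _, fid in scored]
    return ranked.index(parent_id) + 1, ranked[0]


def monte_carlo_cv(
    families: list[Family],
    fps: Mapping[str, Fingerprint],
    params: ScoringParams = ScoringParams(),
    fraction: float = 0.1,
    runs: int = 5,
    seed: int = 0,
    holdout_min: int = 2,
) -> CVReport:
    """Repeated random-subsampling cross-validation over a family set.

    Per run, ``ceil(fraction * n)`` members of each family with at least
    ``holdout_min`` members are held out as queries (families below that
    size are skipped and reported — holding out the only member would
    leave nothing to score against).  Queries are ranked against all
    families with every held-out member removed.  Deterministic for a
    fixed seed.
    """
    if not families:
        raise ValueError("no families supplied")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    stages = {f.stage for f in families}
    stage = stages.pop() if len(stages) == 1 else "mixed"
    fams = sorted(families, key=lambda f: f.family_id)

    eligible = [f for f in fams if len(f.member_ids) >= holdout_min]
    if not eligible:
        raise ValueError("every family is too small to hold out from")

    results: list[RunResult] = []
    for run_idx in range(runs):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), run_idx]).generate_state(1)[0] % (2**31)
        )
        holdout: dict[str, list[str]] = {}
        for fam in eligible:
            members = sorted(fam.member_ids)
            k = math.ceil(fraction * len(members))
            picked = rng.choice(len(members), size=k, replace=False)
            holdout[fam.family_id] = [members[i] for i in sorted(picked)]

        memberships: dict[str, frozenset[str]] = {}
        skipped = [f.family_id for f in fams if len(f.member_ids) < holdout_min]
        for fam in fams:
            remaining = fam.member_ids - frozenset(holdout.get(fam.family_id, ()))
            if remaining:
                memberships[fam.family_id] = remaining
            else:
                skipped.append(fam.family_id)

        n_panel = len(memberships)
        queries = top1 = top4 = 0
        counts = ConfusionCounts()
        for fam in eligible:
            if fam.family_id not in memberships:
                continue
            for qid in holdout[fam.family_id]:
                rank, top_family = _rank_of_parent(
                    fps[qid], fam.family_id, memberships, fps, params
                )
                queries += 1
                if rank == 1:
                    top1 += 1
                    counts += ConfusionCounts(TP=1, TN=n_panel - 1)
                else:
                    counts += ConfusionCounts(FP=1, FN=1, TN=n_panel - 2)
                if rank <= 4:
                    top4 += 1
        results.append(
            RunResult(
                queries=queries,
                top1_hits=top1,
                top4_hits=top4,
                counts=counts,
                mcc=mcc(counts) if queries else float("nan"),
                skipped_families=sorted(set(skipped)),
            )
        )
    return CVReport(family_stage=stage, runs=results)
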