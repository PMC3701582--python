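"""Similarity-to-probability transform and the molecule-family PR-score.

Across a large compound collection, the all-against-all Tanimoto
similarity distribution is sharply concentrated near zero, and its
exceedance curve is well approximated by a half-Gaussian.  A pairwise
similarity ``t`` is therefore converted into the probability that a
random compound pair scores at least as high:

    p(X > t) = exp(-t^2 / (2 h^2))

with bandwidth ``h`` (default 0.125, fitted on a large bioactivity
database).  The Parzen-Rosenblatt molecule-family score (PR-score) of a
query ``x`` against a family ``w = {x_1 .. x_n}`` is the kernel average

    f(x, w) = (1/n) * sum_j p(X > t(x, x_j)),

a number in (0, 1]: small when the query is closely similar to many
members, 1 when it shares nothing with any of them.  The PR-score is
read as a family-level p-value; families scoring at or below ``alpha``
are called significant.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .activity_filter import classify_record
from .fingerprints import tanimoto
from .models import (
    ActivityRecord,
    Family,
    Fingerprint,
    Molecule,
    Prediction,
    ScoringParams,
)


def gaussian_pvalue(t, h: float = 0.125):
    """Probability that a random pairwise similarity exceeds ``t``.

    Strictly decreasing in ``t``; equals 1 at ``t = 0``.  Accepts scalars
    or arrays.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("similarity must lie in [0, 1]")
    out = np.exp(-(t_arr**2) / (2.0 * h * h))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def fit_smoothing_factor(
    similarities: Sequence[float] | np.ndarray,
    grid: np.ndarray | None = None,
) -> float:
    """Fit the Gaussian bandwidth to an observed similarity sample.

    Minimises the squared error between the empirical exceedance
    fraction P(X > x) and ``exp(-x^2 / 2h^2)`` over a fixed grid of x.
    Needs at least 100 values; a constant or all-zero sample carries no
    scale information and is rejected.
    """
    sims = np.asarray(similarities, dtype=float)
    if sims.size < 100:
        raise ValueError("need at least 100 similarity values to fit h")
    if np.any(sims < 0) or np.any(sims > 1):
        raise ValueError("similarities must lie in [0, 1]")
    if np.ptp(sims) == 0:
        raise ValueError("degenerate similarity sample (constant values)")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    exceed = np.array([(sims > x).mean() for x in grid])

    def loss(h: float) -> float:
        model = np.exp(-(grid**2) / (2.0 * h * h))
        return float(np.sum((exceed - model) ** 2))

    res = minimize_scalar(loss, bounds=(1e-3, 2.0), method="bounded")
    return float(res.x)


def pr_score(
    query: Fingerprint,
    family_members: Iterable[Fingerprint],
    params: ScoringParams = ScoringParams(),
) -> float:
    """Parzen-Rosenblatt score of a query against a family's members.

    The arithmetic mean over members of the Gaussian-transformed
    similarity p-value; lower = more significant.
    """
    members = list(family_members)
    if not members:
        raise ValueError("family has no members to score against")
    ts = np.array([tanimoto(query, m) for m in members])
    return float(np.mean(gaussian_pvalue(ts, params.h)))


@dataclass
class PredictionReport:
    """Families that could not be scored (emptied by self-exclusion)."""

    omitted: list[tuple[str, str]] = field(default_factory=list)  # (family_id, reason)


def known_activity_labels(
    activities: Iterable[ActivityRecord] | None,
) -> dict[tuple[str, str], str]:
    """Map (compound_id, target-family id) -> active/inactive from records."""
    if activities is None:
        return {}
    status: dict[tuple[str, str], str] = {}
    for r in activities:
        key = (r.compound_id, r.family_id)
        label = classify_record(r)
        if label == "active":
            status[key] = "active"
        elif key not in status:
            status[key] = "inactive"
    return status


def predict_targets(
    query: Molecule | Fingerprint,
    families: Sequence[Family],
    fps: Mapping[str, Fingerprint],
    params: ScoringParams = ScoringParams(),
    activities: Iterable[ActivityRecord] | None = None,
    report: PredictionReport | None = None,
) -> list[Prediction]:
    """Rank all families for one query by ascending PR-score.

    If the query is itself a member of a family, its fingerprint is
    excluded from that family before scoring (held-out semantics); a
    family emptied by this exclusion is omitted and noted in ``report``.
    Ties are broken by family_id so rankings are deterministic.
    """
    if not families:
        raise ValueError("no families to score against")
    if isinstance(query, Fingerprint):
        qfp = query
        qid = query.compound_id
    else:
        if query.id not in fps:
            raise ValueError(f"no fingerprint for query {query.id!r}")
        qfp = fps[query.id]
        qid = query.id

    known = known_activity_labels(activities)
    scored: list[tuple[float, str, Family]] = []
    for fam in families:
        member_ids = fam.member_ids - {qid}
        if not member_ids:
            if report is not None:
                report.omitted.append((fam.family_id, "emptied by self-exclusion"))
            continue
        missing = [m for m in member_ids if m not in fps]
        if missing:
            raise ValueError(f"family {fam.family_id!r}: no fingerprint for {missing}")
        score = pr_score(qfp, (fps[m] for m in sorted(member_ids)), params)
        scored.append((score, fam.family_id, fam))
    if not scored:
        raise ValueError("every family was emptied by self-exclusion")

    scored.sort(key=lambda s: (s[0], s[1]))
    predictions = []
    for rank, (score, fid, fam) in enumerate(scored, start=1):
        predictions.append(
            Prediction(
                query_id=qid,
                family_id=fid,
                pr_score=score,
                rank=rank,
                significant=score <= params.alpha,
                known_activity=known.get((qid, fam.root_id), "untested"),
                target_name=fam.target_name,
            )
        )
    return predictions
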