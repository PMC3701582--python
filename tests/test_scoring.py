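import math

import numpy as np
import pytest
from scipy import stats

import targetfish as tf
from conftest import make_fingerprint, planted_family_fps, random_fingerprint


def brute_force_pr(query, members, h):
    """Independent oracle: explicit loop, math-library arithmetic only."""
    total = 0.0
    for m in members:
        inter = len(query.features & m.features)
        union = len(query.features | m.features)
        t = inter / union
        total += math.exp(-(t * t) / (2.0 * h * h))
    return total / len(members)


class TestGaussianPvalue:
    def test_zero_similarity_gives_one(self):
        assert tf.gaussian_pvalue(0.0, 0.125) == 1.0

    def test_closed_form_at_h_sqrt2(self):
        assert tf.gaussian_pvalue(0.125 * math.sqrt(2), 0.125) == pytest.approx(
            math.exp(-1), rel=1e-12)

    def test_closed_form_at_unit_similarity(self):
        assert tf.gaussian_pvalue(1.0, 0.125) == pytest.approx(math.exp(-32), rel=1e-12)

    def test_strictly_decreasing_in_t(self):
        ts = np.linspace(0, 1, 101)
        ps = tf.gaussian_pvalue(ts, 0.125)
        assert np.all(np.diff(ps) < 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            tf.gaussian_pvalue(1.5, 0.125)
        with pytest.raises(ValueError):
            tf.gaussian_pvalue(-0.1, 0.125)
        with pytest.raises(ValueError):
            tf.gaussian_pvalue(0.5, 0.0)


class TestBandwidthFit:
    def test_recovers_h_from_exact_exceedance_curve(self):
        # quantile sample whose exceedance curve is exactly exp(-x^2/2h^2):
        # the Rayleigh(h) inverse CDF evaluated on a uniform grid
        h = 0.125
        u = np.linspace(0.0005, 0.9995, 2000)
        sims = np.clip(h * np.sqrt(-2 * np.log1p(-u)), 0, 1)
        assert tf.fit_smoothing_factor(sims) == pytest.approx(h, abs=0.005)

    @pytest.mark.parametrize("h", [0.125, 0.2])
    def test_recovers_h_from_random_sample(self, h):
        rng = np.random.default_rng(123)
        sims = np.clip(stats.rayleigh.rvs(scale=h, size=100_000, random_state=rng), 0, 1)
        assert tf.fit_smoothing_factor(sims) == pytest.approx(h, abs=0.01)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            tf.fit_smoothing_factor(np.zeros(500))
        with pytest.raises(ValueError):
            tf.fit_smoothing_factor(np.full(500, 0.3))
        with pytest.raises(ValueError):
            tf.fit_smoothing_factor(np.linspace(0, 1, 50))  # too few


class TestPRScore:
    def test_family_of_query_copies_scores_e_minus_32(self):
        q = make_fingerprint("q", {1, 2, 3})
        members = [make_fingerprint("a", {1, 2, 3}), make_fingerprint("b", {1, 2, 3})]
        assert tf.pr_score(q, members) == pytest.approx(math.exp(-32), rel=1e-12)

    def test_equals_mean_of_member_pvalues(self):
        q = make_fingerprint("q", set(range(10)))
        m1 = make_fingerprint("a", set(range(5)) | {100, 101, 102, 103, 104})
        m2 = make_fingerprint("b", set(range(8)) | {200, 201})
        p1 = tf.gaussian_pvalue(tf.tanimoto(q, m1), 0.125)
        p2 = tf.gaussian_pvalue(tf.tanimoto(q, m2), 0.125)
        assert tf.pr_score(q, [m1, m2]) == pytest.approx((p1 + p2) / 2, rel=1e-14)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        params = tf.ScoringParams()
        for _ in range(200):
            q = random_fingerprint(rng, "q")
            members = [random_fingerprint(rng, f"m{j}") for j in range(int(rng.integers(1, 12)))]
            assert tf.pr_score(q, members, params) == pytest.approx(
                brute_force_pr(q, members, params.h), abs=1e-12)

    def test_monotone_in_member_similarity(self):
        q = make_fingerprint("q", set(range(20)))
        far = make_fingerprint("far", set(range(100, 120)))
        near = make_fingerprint("near", set(range(15)) | set(range(100, 105)))
        base = [make_fingerprint("x", set(range(10)) | set(range(200, 210)))]
        assert tf.pr_score(q, base + [near]) <= tf.pr_score(q, base + [far])

    def test_invariant_to_duplicating_every_member(self):
        rng = np.random.default_rng(1)
        q = random_fingerprint(rng, "q")
        members = [random_fingerprint(rng, f"m{j}") for j in range(5)]
        assert tf.pr_score(q, members) == pytest.approx(
            tf.pr_score(q, members + members), rel=1e-14)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            tf.pr_score(make_fingerprint("q", {1}), [])

    def test_pvalue_of_tanimoto_is_symmetric_in_molecules(self):
        a = tf.compute_fingerprint(tf.Molecule("a", "CCOC"))
        b = tf.compute_fingerprint(tf.Molecule("b", "CCNC"))
        assert tf.gaussian_pvalue(tf.tanimoto(a, b)) == tf.gaussian_pvalue(tf.tanimoto(b, a))


class TestPredictTargets:
    @pytest.fixture()
    def panel(self):
        rng = np.random.default_rng(3)
        fps = {}
        families = []
        for k in range(4):
            members = planted_family_fps(rng, k, 5)
            fps.update({f.compound_id: f for f in members})
            families.append(tf.Family(f"F{k}", "filtered",
                                      frozenset(f.compound_id for f in members)))
        return families, fps

    def test_ranks_are_a_permutation_and_sorted_by_score(self, panel):
        families, fps = panel
        q = fps["f0m0"]
        preds = tf.predict_targets(q, families, fps)
        assert [p.rank for p in preds] == list(range(1, len(preds) + 1))
        scores = [p.pr_score for p in preds]
        assert scores == sorted(scores)
        assert preds[0].family_id == "F0"  # own family wins despite self-exclusion

    def test_significance_flag_matches_alpha(self, panel):
        families, fps = panel
        preds = tf.predict_targets(fps["f1m2"], families, fps,
                                   tf.ScoringParams(alpha=0.05))
        for p in preds:
            assert p.significant == (p.pr_score <= 0.05)
        assert sum(p.significant for p in preds) == 1  # only the parent family

    def test_self_exclusion_changes_score(self, panel):
        families, fps = panel
        q = fps["f0m0"]
        preds = tf.predict_targets(q, families, fps)
        own = next(p for p in preds if p.family_id == "F0")
        members_without_q = [fps[m] for m in sorted(families[0].member_ids - {"f0m0"})]
        assert own.pr_score == pytest.approx(tf.pr_score(q, members_without_q), rel=1e-14)

    def test_sole_member_family_omitted_and_reported(self, panel):
        families, fps = panel
        solo = tf.Family("solo", "filtered", frozenset({"f0m0"}))
        report = tf.scoring.PredictionReport()
        preds = tf.predict_targets(fps["f0m0"], families + [solo], fps, report=report)
        assert all(p.family_id != "solo" for p in preds)
        assert report.omitted == [("solo", "emptied by self-exclusion")]

    def test_known_activity_annotation(self, panel):
        families, fps = panel
        acts = [tf.ActivityRecord("f0m0", "F1", "IC50", "=", 1.0, "uM"),
                tf.ActivityRecord("f0m0", "F2", "IC50", "=", 900.0, "uM")]
        preds = tf.predict_targets(fps["f0m0"], families, fps, activities=acts)
        by_fam = {p.family_id: p.known_activity for p in preds}
        assert by_fam["F1"] == "active"
        assert by_fam["F2"] == "inactive"
        assert by_fam["F3"] == "untested"

    def test_empty_family_set_rejected(self, panel):
        _, fps = panel
        with pytest.raises(ValueError):
            tf.predict_targets(fps["f0m0"], [], fps)
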