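"""Reliability, validity contrasts, feasibility, retention, brief form."""

import math

import numpy as np
import pytest

from crcdqi.item_bank import load_item_bank
from crcdqi.psychometrics import (
    RetentionThresholds,
    brief_reproducibility,
    feasibility_report,
    involvement_association,
    item_retention_screen,
    knowledge_contrast,
    retest_reliability,
)
from crcdqi.records import Mode

from conftest import TABLE3, make_record


def bivariate_pairs(rng, n, rho, mean=50.0, sd=10.0):
    """(test, retest) pairs with population ICC(2,1) = rho."""
    t = rng.normal(mean, sd, size=n)
    r = mean + rho * (t - mean) + sd * math.sqrt(1 - rho**2) * rng.normal(size=n)
    return list(zip(t, r))


class TestICC:
    def test_perfect_agreement_is_one(self):
        pairs = [(10.0, 10.0), (20.0, 20.0), (35.0, 35.0), (50.0, 50.0)]
        res = retest_reliability(pairs, "k")
        assert res.icc == pytest.approx(1.0)
        assert res.meets_target

    def test_independent_retest_is_near_zero(self):
        rng = np.random.default_rng(7)
        pairs = bivariate_pairs(rng, 500, rho=0.0)
        res = retest_reliability(pairs, "null")
        assert abs(res.icc) < 0.1
        assert res.ci_low <= res.icc <= res.ci_high

    def test_recovery_at_published_reliability_and_sample_size(self):
        """With true ICC 0.87 and n = 71 retest pairs, the estimator is
        unbiased and 0.87 sits inside the central 95% of its sampling
        distribution over 200 replicates."""
        rng = np.random.default_rng(11)
        estimates = [
            retest_reliability(bivariate_pairs(rng, 71, rho=0.87), "g").icc
            for _ in range(200)
        ]
        lo, hi = np.quantile(estimates, [0.025, 0.975])
        assert lo <= 0.87 <= hi
        assert np.mean(estimates) == pytest.approx(0.87, abs=0.03)

    def test_matches_reference_implementation_to_1e9(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(13)
        for _ in range(5):
            n = int(rng.integers(5, 30))
            pairs = bivariate_pairs(rng, n, rho=float(rng.uniform(0, 0.95)))
            ours = retest_reliability(pairs, "x")
            df = pd.DataFrame(
                {
                    "subject": list(range(n)) * 2,
                    "rater": ["t"] * n + ["r"] * n,
                    "score": [p[0] for p in pairs] + [p[1] for p in pairs],
                }
            )
            ref = pingouin.intraclass_corr(
                df, targets="subject", raters="rater", ratings="score"
            ).set_index("Type")
            assert ours.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
            # the reference rounds its CI bounds to 2 decimals
            ref_lo, ref_hi = ref.loc["ICC(A,1)", "CI95"]
            assert ours.ci_low == pytest.approx(ref_lo, abs=6e-3)
            assert ours.ci_high == pytest.approx(ref_hi, abs=6e-3)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            retest_reliability([(1.0, 1.0), (2.0, 2.0)], "k")

    def test_zero_between_subject_variance_reports_zero(self, caplog):
        pairs = [(5.0, 4.0), (4.0, 5.0), (5.0, 4.0), (4.0, 5.0)]
        # subject means all equal -> no between-subject variance
        res = retest_reliability(pairs, "flat")
        assert res.icc == 0.0


class TestKnowledgeContrast:
    def test_identical_cohorts_show_no_difference(self):
        a = [60.0, 70.0, 80.0, 90.0]
        res = knowledge_contrast(a, list(a))
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_da_vs_control_difference_recovered_over_replicates(self, bank):
        """Simulating both arms at the published per-item proportions, the
        estimated mean difference falls inside the published 95% interval
        (12.1%, 22.9%) in at least 90% of 200 replicates."""
        rng = np.random.default_rng(19)
        n_da, counts_da = TABLE3["online_da"]
        n_ct, counts_ct = TABLE3["online_control"]
        p_da = np.array(counts_da) / n_da
        p_ct = np.array(counts_ct) / n_ct
        inside = 0
        for _ in range(200):
            scores_da = 100 * rng.binomial(1, p_da, size=(n_da, 10)).mean(axis=1)
            scores_ct = 100 * rng.binomial(1, p_ct, size=(n_ct, 10)).mean(axis=1)
            diff = knowledge_contrast(scores_da, scores_ct).estimate
            inside += 12.1 <= diff <= 22.9
        assert inside >= 0.90 * 200

    def test_provider_vs_online_direction_and_significance(self, bank):
        rng = np.random.default_rng(23)
        n_pr, counts_pr = TABLE3["provider"]
        p_pr = np.array(counts_pr) / n_pr
        n_on = TABLE3["online_da"][0] + TABLE3["online_control"][0]
        p_on = (np.array(TABLE3["online_da"][1]) + np.array(TABLE3["online_control"][1])) / n_on
        scores_pr = 100 * rng.binomial(1, p_pr, size=(n_pr, 10)).mean(axis=1)
        scores_on = 100 * rng.binomial(1, p_on, size=(n_on, 10)).mean(axis=1)
        res = knowledge_contrast(scores_pr, scores_on, "provider-vs-online")
        assert res.estimate > 0
        assert res.p_value < 0.001

    def test_degenerate_cohorts_rejected(self):
        with pytest.raises(ValueError):
            knowledge_contrast([50.0], [60.0, 70.0])


def fisher_two_sided_enumeration(a, b, c, d):
    """Exact two-sided p by hypergeometric enumeration (point-mass rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def pmf(x):
        if x < max(0, c1 - r2) or x > min(r1, c1):
            return 0.0
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(0, min(r1, c1) + 1) if pmf(x) <= p_obs * (1 + 1e-9))


class TestInvolvementAssociation:
    def test_equal_proportions_give_p_one(self):
        hq = [True] * 10 + [False] * 10
        doc = ([True] * 5 + [False] * 5) * 2
        assert involvement_association(hq, doc).p_value == pytest.approx(1.0)

    def test_published_marginals_are_not_significant(self):
        # 29.7% of 32 high-quality vs 38.9% of 119 others report a
        # doctor-made decision
        a, c = round(0.297 * 32), round(0.389 * 119)
        hq = [True] * 32 + [False] * 119
        doc = [True] * a + [False] * (32 - a) + [True] * c + [False] * (119 - c)
        res = involvement_association(hq, doc)
        assert res.p_value > 0.05
        assert res.mean_a < res.mean_b  # high quality -> fewer doctor-made

    def test_perfect_association_is_significant(self):
        hq = [True] * 10 + [False] * 10
        doc = [True] * 10 + [False] * 10
        res = involvement_association(hq, doc)
        assert res.p_value < 0.001
        assert res.p_value == pytest.approx(
            fisher_two_sided_enumeration(10, 0, 0, 10), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = int(rng.integers(3, 25)), int(rng.integers(3, 25))
        a = int(rng.integers(0, n1 + 1))
        c = int(rng.integers(0, n0 + 1))
        if (a == 0 and c == 0) or (a == n1 and c == n0):
            a = min(a + 1, n1)
        hq = [True] * n1 + [False] * n0
        doc = [True] * a + [False] * (n1 - a) + [True] * c + [False] * (n0 - c)
        res = involvement_association(hq, doc)
        expected = fisher_two_sided_enumeration(a, n1 - a, c, n0 - c)
        assert res.p_value == pytest.approx(expected, abs=1e-10)


class TestFeasibility:
    def test_fully_complete_cohort_has_zero_missing(self, bank):
        cohort = [make_record(bank, f"R{i}") for i in range(10)]
        rep = feasibility_report(cohort, bank)
        assert rep.knowledge_missing_pct == 0.0
        assert rep.goals_missing_pct == 0.0

    def test_response_rate_arithmetic(self, bank):
        cohort = [make_record(bank, f"R{i}") for i in range(115)]
        rep = feasibility_report(cohort, bank, invited=193)
        assert rep.response_rate_pct == pytest.approx(100 * 115 / 193)
        assert round(rep.response_rate_pct, 1) == 59.6

    def test_mode_stratified_missingness(self, bank):
        cohort = []
        for i in range(20):
            rec = make_record(bank, f"ON{i}", mode=Mode.ONLINE)
            cohort.append(rec)
        for i in range(20):
            # mail respondents leave 2 or 3 items blank
            rec = make_record(bank, f"ML{i}", n_correct=8 - i % 2, mode=Mode.MAIL)
            cohort.append(rec)
        rep = feasibility_report(cohort, bank)
        assert rep.knowledge_missing_by_mode["online"] == 0.0
        assert rep.knowledge_missing_by_mode["mail"] == pytest.approx(25.0)
        assert rep.mode_contrast_knowledge is not None
        assert rep.mode_contrast_knowledge.p_value < 0.001


class TestRetentionScreen:
    def _cohort(self, bank, n=40, p_correct=0.5, top_share=0.0, top3_goal=None):
        rng = np.random.default_rng(43)
        cohort = []
        for i in range(n):
            responses = {}
            for item in bank.knowledge_items:
                correct = rng.random() < p_correct
                responses[item.item_id] = (
                    item.correct_option
                    if correct
                    else next(o for o in item.options if o != item.correct_option)
                )
            ratings = {}
            for g in bank.goal_ids:
                if rng.random() < top_share:
                    ratings[g] = 10
                else:
                    ratings[g] = int(rng.integers(0, 10))
            top = frozenset({top3_goal}) if top3_goal else frozenset()
            cohort.append(
                make_record(bank, f"R{i}", goal_ratings=ratings, top_three=top)
            )
            cohort[-1].knowledge_responses = responses
        return cohort

    def test_item_above_85_pct_flagged_too_easy(self, bank):
        cohort = self._cohort(bank, p_correct=0.95)
        diags = {d.item_id: d for d in item_retention_screen(cohort, bank)}
        flagged = [d for d in diags.values() if d.kind == "knowledge" and d.reasons]
        assert flagged and all("too easy" in d.reasons[0] for d in flagged)

    def test_goal_with_ceiling_but_frequent_top_three_retained(self, bank):
        cohort = self._cohort(bank, top_share=0.64, top3_goal="G_KNOW")
        diags = {d.item_id: d for d in item_retention_screen(cohort, bank)}
        d = diags["G_KNOW"]
        assert any("ceiling" in r for r in d.reasons)
        assert d.flag.value == "retain"  # saved by top-three endorsement

    def test_goal_rarely_in_top_three_flagged_drop(self, bank):
        cohort = self._cohort(bank, top3_goal="G_KNOW")  # others never named
        diags = {d.item_id: d for d in item_retention_screen(cohort, bank)}
        assert diags["G_COST"].flag.value == "drop"

    def test_redundant_goal_pair_flagged(self, bank):
        cohort = self._cohort(bank)
        for rec in cohort:  # make G_PAIN a copy of G_COST
            rec.goal_ratings["G_PAIN"] = rec.goal_ratings["G_COST"]
            rec.top_three = frozenset({"G_PAIN", "G_COST"})
        diags = {d.item_id: d for d in item_retention_screen(cohort, bank)}
        assert diags["G_PAIN"].redundancy_partner == "G_COST"
        assert diags["G_PAIN"].redundancy_r == pytest.approx(1.0)

    def test_small_cohort_rejected(self, bank):
        with pytest.raises(ValueError, match="at least"):
            item_retention_screen([make_record(bank)] * 10, bank)

    def test_flags_deterministic_for_fixed_inputs(self, bank):
        cohort = self._cohort(bank, p_correct=0.9, top_share=0.6)
        first = item_retention_screen(cohort, bank, RetentionThresholds())
        second = item_retention_screen(cohort, bank, RetentionThresholds())
        assert first == second


class TestBriefReproducibility:
    def test_brief_equal_to_full_gives_r_one(self, bank):
        cfg = bank.to_config()
        cfg["knowledge_items"] = cfg["knowledge_items"][:5]
        five_bank = load_item_bank(cfg)
        rng = np.random.default_rng(47)
        cohort = []
        for i in range(30):
            n_corr = int(rng.integers(0, 6))
            cohort.append(make_record(five_bank, f"R{i}", n_correct=n_corr, n_wrong=5 - n_corr))
        rep = brief_reproducibility(cohort, five_bank)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_independent_items_give_intermediate_r(self, bank):
        n, counts = TABLE3["online_da"]
        rng = np.random.default_rng(53)
        p = np.array(counts) / n
        cohort = []
        for i in range(n):
            correct = rng.random(10) < p
            responses = {
                item.item_id: (
                    item.correct_option
                    if correct[j]
                    else next(o for o in item.options if o != item.correct_option)
                )
                for j, item in enumerate(bank.knowledge_items)
            }
            rec = make_record(bank, f"R{i}")
            rec.knowledge_responses = responses
            cohort.append(rec)
        rep = brief_reproducibility(cohort, bank)
        assert 0.0 < rep.pearson_r < 1.0
        again = brief_reproducibility(cohort, bank)
        assert again.pearson_r == rep.pearson_r

    def test_constant_scores_reported_as_undefined(self, bank):
        cohort = [make_record(bank, f"R{i}", n_correct=10) for i in range(5)]
        rep = brief_reproducibility(cohort, bank)
        assert rep.pearson_r is None
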