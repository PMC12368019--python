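"""Timelines, rater agreement, the nonparametric suite, sedation rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seeme.clinical import (
    ClinicalScore,
    PatientTimeline,
    RaterRatings,
    SedationRecord,
    auc_from_scores,
    build_timeline,
    chi_square_test,
    classify_sedation,
    clinical_detection_day,
    cohort_detection_summary,
    detection_lead_time,
    dunn_bonferroni,
    kruskal_p_from_stat,
    kruskal_wallis,
    normality_check,
    rater_agreement,
    rater_video_decision,
)
from seeme.detection import VideoResult


def _vr(command="EYES", positive=True):
    return VideoResult(
        command_type=command, n_trials=10, n_positive=3 if positive else 1,
        fraction_positive=0.3 if positive else 0.1,
        max_amplitude=500.0 if positive else None, seeme_positive=positive,
    )


def _gcs_e(day, value, pid="p1"):
    return ClinicalScore(pid, day, "GCS_E", value)


class TestTimelines:
    def test_same_day_detection_gives_zero_lead(self):
        tl = build_timeline("p13", [(12, _vr())], [_gcs_e(12, 3)])
        assert detection_lead_time(tl, "eye") == 0

    def test_video_detection_before_exam(self):
        """Video SeeMe+ on day 19, eye-opening on exam day 22 -> lead 3."""
        scores = [_gcs_e(10, 2), _gcs_e(22, 3)]
        tl = build_timeline("p2", [(19, _vr())], scores)
        assert detection_lead_time(tl, "eye") == 3

    def test_missing_clinical_day_undefined(self):
        tl = build_timeline("p", [(5, _vr())], [_gcs_e(9, 2)])
        assert detection_lead_time(tl, "eye") is None

    def test_first_crossing_day(self):
        scores = [_gcs_e(1, 1), _gcs_e(5, 2), _gcs_e(8, 2), _gcs_e(12, 3)]
        assert clinical_detection_day(scores, "eye") == 12

    def test_never_crossing_undefined(self):
        assert clinical_detection_day([_gcs_e(3, 2)], "eye") is None

    def test_mouth_family_uses_crsr_auditory(self):
        scores = [ClinicalScore("p13", 37, "CRSR_auditory", 3)]
        assert clinical_detection_day(scores, "mouth") == 37

    def test_intra_day_best_result_collapse(self):
        tl = build_timeline(
            "p", [(4, _vr(positive=False)), (4, _vr(positive=True))], []
        )
        assert tl.first_seeme_day["eye"] == 4

    def test_cohort_summary_exact_on_known_days(self):
        tls = [
            build_timeline("a", [(10, _vr())], [_gcs_e(14, 3, "a")]),
            build_timeline("b", [(20, _vr())], [_gcs_e(22, 3, "b")]),
            build_timeline("c", [(7, _vr())], []),  # video-only
        ]
        s = cohort_detection_summary(tls, "eye")
        assert s["n_both"] == 2 and s["n_seeme_only"] == 1
        assert s["seeme_day_mean"] == 15.0
        assert s["lead_time_mean"] == 3.0
        assert s["lead_time_sd"] == pytest.approx(np.std([4, 2], ddof=1))


class TestRaters:
    def test_either_rater_rule_and_three_of_ten(self):
        a = np.zeros(10, bool); a[:3] = True
        b = np.zeros(10, bool)
        trial_pos, video_pos = rater_video_decision(RaterRatings(a, b))
        assert trial_pos.sum() == 3 and video_pos

    def test_all_no_is_negative(self):
        _, video_pos = rater_video_decision(
            RaterRatings(np.zeros(10, bool), np.zeros(10, bool))
        )
        assert not video_pos

    def test_two_positive_trials_below_threshold(self):
        a = np.zeros(10, bool); a[0] = True
        b = np.zeros(10, bool); b[1] = True
        trial_pos, video_pos = rater_video_decision(RaterRatings(a, b))
        assert trial_pos.sum() == 2 and not video_pos

    def test_missing_rater_degrades_with_warning(self):
        a = np.zeros(10, bool); a[:4] = True
        with pytest.warns(UserWarning, match="single rater"):
            _, video_pos = rater_video_decision(RaterRatings(a, None))
        assert video_pos

    def test_perfect_agreement_kappa_one(self):
        a = np.array([1, 0, 1, 0, 1], bool)
        agree, kappa = rater_agreement(RaterRatings(a, a.copy()))
        assert agree == 1.0 and kappa == pytest.approx(1.0)

    def test_hand_computed_kappa(self):
        """2x2 counts yes/yes=4, yes/no=1, no/yes=1, no/no=4:
        p_o = 0.8, p_e = 0.5 -> kappa = 0.6."""
        a = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)
        b = np.array([1, 1, 1, 1, 0, 1, 0, 0, 0, 0], bool)
        agree, kappa = rater_agreement(RaterRatings(a, b))
        assert agree == pytest.approx(0.8)
        assert kappa == pytest.approx(0.6)

    def test_kappa_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        a, b = rng.random(60) < 0.4, rng.random(60) < 0.6
        _, kappa = rater_agreement(RaterRatings(a, b))
        assert kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_independent_raters_null_kappa(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(10000) < 0.5, rng.random(10000) < 0.5
        _, kappa = rater_agreement(RaterRatings(a, b))
        assert abs(kappa) < 0.05

    def test_degenerate_marginals_nan(self):
        ones = np.ones(10, bool)
        with pytest.warns(UserWarning, match="degenerate"):
            _, kappa = rater_agreement(RaterRatings(ones, ones.copy()))
        assert np.isnan(kappa)


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        h, df, p = kruskal_wallis([1, 1, 1], [1, 1, 1], [1, 1], [1])
        assert h == 0.0 and df == 3 and p == 1.0

    def test_hand_rank_example(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: mean ranks 2/5/8 -> H = 7.2."""
        h, df, _ = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2)
        assert df == 2

    def test_printed_tail_probabilities(self):
        assert kruskal_p_from_stat(16.84, 3) == pytest.approx(7.6e-4, rel=0.02)
        assert kruskal_p_from_stat(16.35, 3) == pytest.approx(9.6e-4, rel=0.02)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3])

    def test_two_group_h_equals_squared_ranksum_z(self):
        """For k = 2, H equals the squared normal deviate of the
        Wilcoxon rank-sum test (asymptotically)."""
        from scipy import stats

        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 80), rng.normal(0.6, 1, 90)
        h, _, _ = kruskal_wallis(a, b)
        z = stats.norm.isf(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
        assert h == pytest.approx(z**2, rel=0.05)


class TestDunn:
    def test_identical_groups_all_one(self):
        p = dunn_bonferroni([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert (p == 1.0).all()

    def test_adjustment_is_three_times_raw(self):
        from scipy import stats

        groups = ([1, 4, 7, 3], [2, 8, 5, 6], [9, 10, 12, 11])
        adj = dunn_bonferroni(*groups)
        # direct Dunn z for pair (0, 1), no ties
        pooled = np.concatenate(groups)
        n = len(pooled)
        ranks = stats.rankdata(pooled)
        r0, r1 = ranks[:4].mean(), ranks[4:8].mean()
        se = np.sqrt(n * (n + 1) / 12.0 * (2 / 4))
        raw = 2 * stats.norm.sf(abs(r0 - r1) / se)
        assert adj[0, 1] == pytest.approx(min(1.0, 3 * raw))

    def test_separated_groups_significant(self):
        """Widely separated groups: every pair significant.  Rank-based z
        saturates with group size, so adjacent pairs need n = 20 per
        group to clear 0.01 after the x3 Bonferroni factor."""
        p = dunn_bonferroni(
            list(range(1, 21)), list(range(101, 121)), list(range(201, 221))
        )
        off_diag = p[~np.eye(3, dtype=bool)]
        assert (off_diag < 0.01).all()
        # at n = 10 the extreme pair is still significant, adjacent at 0.05
        p10 = dunn_bonferroni(
            list(range(1, 11)), list(range(101, 111)), list(range(201, 211))
        )
        assert p10[0, 2] < 0.01 and p10[0, 1] < 0.05

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            dunn_bonferroni([1, 2], [3, 4])


class TestChiSquare:
    def test_uniform_table(self):
        stat, df, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_perfect_association_hand_computed(self):
        """[[20,0],[0,20]]: all expected counts 10 -> statistic 40."""
        stat, df, _ = chi_square_test([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert df == 1

    def test_two_by_three_df(self):
        _, df, _ = chi_square_test([[5, 6, 7], [8, 9, 10]])
        assert df == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test([[0, 0], [5, 5]])


class TestAUC:
    def test_perfect_separation(self):
        auc, _, _ = auc_from_scores([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0

    def test_interleaved_labels_by_pair_counting(self):
        # pos scores {1,3} vs neg {2,4}: wins 1 of 4 pairs
        auc, _, _ = auc_from_scores([1, 2, 3, 4], [1, 0, 1, 0])
        assert auc == 0.25

    def test_balanced_split_is_chance(self):
        auc, _, _ = auc_from_scores([1, 2, 3, 4], [1, 0, 0, 1])
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(4, 30)
            scores = rng.integers(0, 10, n).astype(float)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            auc, _, _ = auc_from_scores(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            pairs = [
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos for q in neg
            ]
            assert auc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        a1, _, _ = auc_from_scores(scores, labels)
        a2, _, _ = auc_from_scores(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_from_scores([1, 2, 3], [1, 1, 1])


class TestNormalityCheck:
    def test_normal_samples_mostly_pass(self):
        rng = np.random.default_rng(21)
        pvals = [normality_check(rng.normal(0, 1, 200))[1] for _ in range(100)]
        assert np.mean(np.array(pvals) > 0.05) >= 0.9

    def test_exponential_sample_fails(self):
        rng = np.random.default_rng(22)
        _, p, _ = normality_check(rng.exponential(1.0, 500))
        assert p < 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            normality_check(np.full(20, 3.0))


class TestSedation:
    def _rec(self, drug, rate, unit):
        return SedationRecord("p", "2023-01-01T10:00", drug, rate, unit)

    def test_propofol_alone_below_threshold_is_light(self):
        recs = [self._rec("propofol", 40.0, "ug/kg/min")]
        assert classify_sedation(recs) == "light"

    def test_propofol_with_dexmedetomidine_synergy_is_deep(self):
        recs = [
            self._rec("propofol", 40.0, "ug/kg/min"),
            self._rec("dexmedetomidine", 0.6, "ug/kg/h"),
        ]
        assert classify_sedation(recs) == "deep"

    def test_fentanyl_analgesic_dose_is_light(self):
        assert classify_sedation([self._rec("fentanyl", 1.0, "mcg/kg/h")]) == "light"

    def test_no_infusions_is_none(self):
        assert classify_sedation([]) == "none"
        assert classify_sedation([self._rec("propofol", 0.0, "ug/kg/min")]) == "none"

    def test_unknown_drug_rejected(self):
        with pytest.raises(ValueError, match="unknown drug"):
            classify_sedation([self._rec("ketamine", 1.0, "mg/kg/h")])

    def test_wrong_unit_rejected(self):
        with pytest.raises(ValueError, match="invalid for propofol"):
            self._rec("propofol", 40.0, "mg/kg/h")

    @given(
        prop=st.floats(0, 100), dex=st.floats(0, 2),
        mid=st.floats(0, 0.5), fen=st.floats(0, 5),
        bump=st.sampled_from(["propofol", "dexmedetomidine", "midazolam", "fentanyl"]),
        delta=st.floats(0.01, 50),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_dose(self, prop, dex, mid, fen, bump, delta):
        """Raising any infusion rate never moves deep -> light."""
        rates = {"propofol": prop, "dexmedetomidine": dex,
                 "midazolam": mid, "fentanyl": fen}
        units = {"propofol": "ug/kg/min", "dexmedetomidine": "ug/kg/h",
                 "midazolam": "mg/kg/h", "fentanyl": "ug/kg/h"}
        recs = [self._rec(d, r, units[d]) for d, r in rates.items()]
        before = classify_sedation(recs)
        rates[bump] += delta
        recs2 = [self._rec(d, r, units[d]) for d, r in rates.items()]
        after = classify_sedation(recs2)
        order = {"none": 0, "light": 1, "deep": 2}
        assert order[after] >= order[before]
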