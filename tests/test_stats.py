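"""Statistical engine: AUROC, Youden, CIs, DeLong, McNemar, reader tables."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from crossrad.stats import (
    ConfusionCounts,
    ReaderRecord,
    auroc,
    clopper_pearson_ci,
    confusion_at_threshold,
    delong_test,
    dichotomize_scores,
    mcnemar_test,
    metrics_from_confusion,
    reader_study_table,
    youden_cutoff,
)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_pair_counting(self):
        # pos {0.9, 0.4}, neg {0.7, 0.3}: 3 of 4 pairs ordered correctly
        assert auroc([0.9, 0.4, 0.7, 0.3], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_equals_trapezoidal_roc_area(self):
        """Mann-Whitney computation == sklearn's trapezoidal ROC area on 200
        random instances with ties, to 1e-12."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(8, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert abs(auroc(scores, labels) - roc_auc_score(labels, scores)) < 1e-12


class TestYouden:
    def test_perfect_separation_has_j_one(self):
        thr, j = youden_cutoff([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert j == pytest.approx(1.0)
        assert 0.2 < thr <= 0.8

    def test_uninformative_scores(self):
        _, j = youden_cutoff([0.5] * 6, [1, 0, 1, 0, 0, 1])
        assert j == pytest.approx(0.0)

    def test_tie_broken_toward_sensitivity(self):
        # J = 2/3 at thresholds 0.8 and 0.4; sensitivity picks 0.4
        thr, j = youden_cutoff([0.9, 0.8, 0.4, 0.7, 0.3, 0.2], [1, 1, 1, 0, 0, 0])
        assert j == pytest.approx(2 / 3)
        assert thr == pytest.approx(0.4)

    def test_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(6, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)
            thr, j = youden_cutoff(scores, labels)
            # independent exhaustive sweep
            best_j = -2.0
            for t in np.unique(scores):
                pred = scores >= t
                sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
                spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                best_j = max(best_j, sens + spec - 1.0)
            assert j == pytest.approx(best_j, abs=1e-12)


class TestConfusionMetrics:
    def test_reader_one_unassisted_counts(self):
        """13 TP / 21 FP / 18 FN / 89 TN: sens 41.9, spec 80.9, PPV 38.2,
        NPV 83.2 (percentages to one decimal)."""
        ms = metrics_from_confusion(ConfusionCounts(tp=13, fp=21, fn=18, tn=89))
        assert round(100 * ms.sensitivity, 1) == 41.9
        assert round(100 * ms.specificity, 1) == 80.9
        assert round(100 * ms.ppv, 1) == 38.2
        assert round(100 * ms.npv, 1) == 83.2

    def test_f1_is_harmonic_mean_of_sens_and_ppv(self):
        # sens 0.658, PPV 0.709 -> F1 0.683
        f1 = 2 * 0.658 * 0.709 / (0.658 + 0.709)
        assert round(f1, 3) == 0.683
        ms = metrics_from_confusion(ConfusionCounts(tp=658, fp=270, fn=342, tn=730))
        expected = 2 * ms.ppv * ms.sensitivity / (ms.ppv + ms.sensitivity)
        assert ms.f1 == pytest.approx(expected)

    def test_undefined_sensitivity_is_explicit(self):
        ms = metrics_from_confusion(ConfusionCounts(tp=0, fp=3, fn=0, tn=7))
        assert ms.sensitivity is None
        assert "sensitivity" in ms.undefined
        assert ms.specificity == pytest.approx(0.7)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionCounts(0, 0, 0, 0))

    def test_point_estimates_inside_cis(self):
        ms = metrics_from_confusion(ConfusionCounts(tp=13, fp=21, fn=18, tn=89))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            lo, hi = getattr(ms, f"{name}_ci")
            assert lo <= getattr(ms, name) <= hi


class TestClopperPearson:
    def test_reproduces_reference_interval_13_of_31(self):
        """Matches R binom.test(13, 31) exactly; the reference report's
        (24.6, 60.9)% within one unit of its last printed digit (its lower
        bound appears double-rounded: the exact value is 24.548)."""
        lo, hi = clopper_pearson_ci(13, 31)
        assert lo == pytest.approx(0.2454760, abs=1e-6)
        assert hi == pytest.approx(0.6092408, abs=1e-6)
        assert 100 * lo == pytest.approx(24.6, abs=0.1)
        assert 100 * hi == pytest.approx(60.9, abs=0.1)

    def test_boundaries(self):
        assert clopper_pearson_ci(0, 10)[0] == 0.0
        assert clopper_pearson_ci(10, 10)[1] == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(5, 3)

    def test_coverage_at_nominal_level(self):
        """Over 2000 simulated binomials (n=31, p=0.42) the 95% interval
        covers the truth in at least 94% of draws (exact intervals are
        conservative)."""
        rng = np.random.default_rng(5)
        n, p = 31, 0.42
        covered = 0
        draws = rng.binomial(n, p, size=2000)
        for k in draws:
            lo, hi = clopper_pearson_ci(int(k), n)
            covered += lo <= p <= hi
        assert covered / 2000 >= 0.94


class TestDelong:
    def test_identical_classifiers(self):
        rng = np.random.default_rng(1)
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        res = delong_test(s, s, y)
        assert res.diff == 0.0
        assert res.p == 1.0

    def test_auc_consistency(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(40), rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        res = delong_test(a, b, y)
        assert abs(res.auc_a - auroc(a, y)) < 1e-12
        assert abs(res.auc_b - auroc(b, y)) < 1e-12

    def test_agrees_with_permutation_oracle(self):
        """On 30 paired cases the DeLong p tracks a 20000-resample
        sign-flipping permutation test (within 0.02 on this mid-range
        instance; the approximation is coarser in the far tail)."""
        rng = np.random.default_rng(3)
        n = 30
        y = np.array([1] * 12 + [0] * 18)
        signal = y * 0.35
        a = rng.random(n) * 0.8 + signal
        b = rng.random(n)
        res = delong_test(a, b, y)
        observed = abs(res.diff)
        count = 0
        n_perm = 20_000
        flips = rng.random((n_perm, n)) < 0.5
        for f in flips:
            aa = np.where(f, b, a)
            bb = np.where(f, a, b)
            if abs(auroc(aa, y) - auroc(bb, y)) >= observed - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert abs(res.p - p_perm) < 0.02

    def test_null_rejection_rate_calibrated(self):
        """Under the null (independent random score sets) the fraction of
        p < 0.05 over 500 simulations lies in [0.03, 0.08]."""
        rng = np.random.default_rng(4)
        y = np.array([1] * 20 + [0] * 40)
        rejections = 0
        for _ in range(500):
            a = rng.random(60)
            b = rng.random(60)
            if delong_test(a, b, y).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 500 <= 0.08

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.3], [1, 0])


class TestMcNemar:
    def test_symmetric_discordance_capped_at_one(self):
        assert mcnemar_test(5, 5) == 1.0

    def test_exact_binomial_value(self):
        # 2 * (C(12,0) + C(12,1) + C(12,2)) / 2^12 = 158/4096
        assert mcnemar_test(10, 2) == pytest.approx(158 / 4096)

    def test_no_discordance(self):
        assert mcnemar_test(0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test(-1, 2)

    def test_large_sample_uses_continuity_corrected_chi2(self):
        p = mcnemar_test(30, 10)
        chi2 = (abs(30 - 10) - 1) ** 2 / 40
        assert p == pytest.approx(float(sps.chi2.sf(chi2, 1)))

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(10, 2), (3, 7), (0, 5), (8, 8)]:
            table = [[0, b], [c, 0]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_test(b, c) == pytest.approx(float(expected))


class TestDichotomize:
    def test_boundary_three_is_normal(self):
        assert dichotomize_scores([3])[0] == 0

    def test_boundary_four_is_fracture(self):
        assert dichotomize_scores([4])[0] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_scores([6])

    def test_full_scale(self):
        assert dichotomize_scores([1, 2, 3, 4, 5]).tolist() == [0, 0, 0, 1, 1]


def synthetic_reader(counts, n_pos=31, n_neg=110, reader_id="r1", session2_equal=True, seed=0):
    """Build records realizing given session-1 confusion counts (tp, fp, fn, tn)."""
    tp, fp, fn, tn = counts
    assert tp + fn == n_pos and fp + tn == n_neg
    rng = np.random.default_rng(seed)
    records = []
    i = 0
    for truth, score, n in [(1, 5, tp), (1, 2, fn), (0, 4, fp), (0, 1, tn)]:
        for _ in range(n):
            s2 = score if session2_equal else int(rng.integers(1, 6))
            records.append(ReaderRecord(f"c{i:03d}", truth, score, s2, reader_id))
            i += 1
    return records


class TestReaderStudy:
    def test_identity_sessions_give_zero_deltas_and_p_one(self):
        records = synthetic_reader((13, 21, 18, 89))
        table = reader_study_table(records)
        for _, row in table.iterrows():
            if row.metric in ("sensitivity", "specificity", "auroc"):
                assert row.session1 == pytest.approx(row.session2)
                assert row.p_value == pytest.approx(1.0)

    def test_reproduces_reader_one_unassisted_row(self):
        records = synthetic_reader((13, 21, 18, 89))
        table = reader_study_table(records).set_index("metric")
        assert round(100 * table.loc["sensitivity", "session1"], 1) == 41.9
        assert round(100 * table.loc["specificity", "session1"], 1) == 80.9
        assert round(100 * table.loc["ppv", "session1"], 1) == 38.2
        assert round(100 * table.loc["npv", "session1"], 1) == 83.2

    def test_auroc_invariant_to_monotone_relabeling(self):
        records = synthetic_reader((13, 21, 18, 89), session2_equal=False, seed=3)
        table1 = reader_study_table(records).set_index("metric")
        relabeled = [
            ReaderRecord(r.case_id, r.truth,
                         {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}[r.session1_score],
                         min(5, r.session2_score + 0), r.reader_id)
            for r in records
        ]
        table2 = reader_study_table(relabeled).set_index("metric")
        assert 0.0 <= table1.loc["auroc", "session1"] <= 1.0
        assert table1.loc["auroc", "session1"] == pytest.approx(table2.loc["auroc", "session1"])

    def test_purity_same_inputs_same_output(self):
        records = synthetic_reader((13, 21, 18, 89), session2_equal=False, seed=9)
        t1 = reader_study_table(records)
        t2 = reader_study_table(records)
        assert t1.equals(t2)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            reader_study_table([])


def test_confusion_at_threshold_consistency():
    scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
    labels = [1, 1, 1, 0, 0, 0]
    c = confusion_at_threshold(scores, labels, 0.75)
    assert (c.tp, c.fp, c.fn, c.tn) == (2, 0, 1, 3)
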