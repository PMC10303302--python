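import numpy as np
import pytest

from vffr import (
    ConfusionMatrix,
    PairedCohort,
    bland_altman,
    clopper_pearson,
    compare_methods,
    confusion_at_cutoff,
    correlation,
    diagnostic_indices,
    roc_analysis,
)
from vffr.diagnostics import mann_whitney_auc


def make_cohort(index, ffr, ids=None):
    index = np.asarray(index, dtype=float)
    if ids is None:
        ids = np.arange(index.size)
    return PairedCohort(np.asarray(ids), index, np.asarray(ffr, dtype=float))


def random_cohort(rng, n=30):
    ffr = rng.uniform(0.45, 1.0, n)
    index = np.clip(ffr + rng.normal(0, 0.08, n), 0.21, 1.0)
    # ensure both classes present
    ffr[0], ffr[1] = 0.6, 0.95
    return make_cohort(index, ffr)


class TestConfusion:
    def test_perfect_agreement_has_no_errors(self):
        vals = [0.6, 0.7, 0.85, 0.9]
        cm = confusion_at_cutoff(make_cohort(vals, vals), 0.80)
        assert cm.fp == cm.fn == 0
        assert cm.tp == 2 and cm.tn == 2

    def test_cutoff_zero_calls_nothing_positive(self):
        cm = confusion_at_cutoff(make_cohort([0.5, 0.9], [0.5, 0.9]), 0.0)
        assert cm.tp == cm.fp == 0

    def test_matches_per_record_tabulation(self, rng):
        cohort = random_cohort(rng, 50)
        cm = confusion_at_cutoff(cohort, 0.80)
        tp = fp = tn = fn = 0
        for x, y in zip(cohort.index_value, cohort.invasive_ffr):
            pred, truth = x <= 0.80, y <= 0.80
            tp += pred and truth
            fp += pred and not truth
            tn += not pred and not truth
            fn += not pred and truth
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x,n,lo,hi",
        [
            (34, 36, 0.813, 0.993),
            (28, 29, 0.822, 0.999),
            (6, 7, 0.421, 0.996),
        ],
    )
    def test_frozen_intervals(self, x, n, lo, hi):
        got = clopper_pearson(x, n)
        assert got[0] == pytest.approx(lo, abs=5e-4)
        assert got[1] == pytest.approx(hi, abs=5e-4)

    def test_boundaries_exact(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestDiagnosticIndices:
    def test_perfect_classifier(self):
        d = diagnostic_indices(ConfusionMatrix(tp=10, fp=0, tn=10, fn=0))
        assert d.sensitivity.value == 100.0
        assert d.specificity.value == 100.0
        assert d.youden == pytest.approx(1.0)

    def test_identities_hold(self, rng):
        for _ in range(25):
            tp, fp, tn, fn = rng.integers(1, 40, 4)
            cm = ConfusionMatrix(int(tp), int(fp), int(tn), int(fn))
            d = diagnostic_indices(cm)
            sens, spec = d.sensitivity.value / 100, d.specificity.value / 100
            assert d.accuracy.value / 100 * cm.n == pytest.approx(tp + tn)
            assert d.youden == pytest.approx(sens + spec - 1.0)
            assert d.plr.value == pytest.approx(sens / (1 - spec))
            assert d.nlr.value == pytest.approx((1 - sens) / spec)
            assert d.false_discovery_rate_pct == pytest.approx(100 - d.ppv.value)
            assert d.false_omission_rate_pct == pytest.approx(100 - d.npv.value)
            for est in (d.accuracy, d.sensitivity, d.specificity, d.ppv, d.npv, d.plr, d.nlr):
                assert est.lo <= est.value <= est.hi

    def test_zero_denominator_flagged_undefined(self):
        d = diagnostic_indices(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert d.ppv.value is None
        assert d.plr.value is None


class TestRoc:
    def test_perfect_separation(self):
        cohort = make_cohort([0.5, 0.55, 0.6, 0.9, 0.92, 0.95], [0.6, 0.6, 0.6, 0.9, 0.9, 0.9])
        assert roc_analysis(cohort).auc == 1.0

    def test_all_ties_give_half(self):
        cohort = make_cohort([0.7] * 8, [0.6] * 4 + [0.9] * 4)
        assert roc_analysis(cohort).auc == 0.5

    def test_auc_equals_pair_counting_oracle(self):
        index = [0.55, 0.61, 0.66, 0.70, 0.72, 0.74, 0.79, 0.81, 0.84, 0.86, 0.90, 0.74]
        ffr = [0.60, 0.65, 0.70, 0.75, 0.78, 0.80, 0.79, 0.85, 0.88, 0.90, 0.95, 0.83]
        cohort = make_cohort(index, ffr)
        pos = cohort.truth_positive
        scores = -cohort.index_value
        conc = 0.0
        npairs = 0
        for sp in scores[pos]:
            for sn in scores[~pos]:
                npairs += 1
                conc += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        assert roc_analysis(cohort).auc == pytest.approx(conc / npairs)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        cohort = random_cohort(rng, 40)
        auc = roc_analysis(cohort).auc
        assert auc == pytest.approx(
            roc_auc_score(cohort.truth_positive, -cohort.index_value)
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_analysis(make_cohort([0.5, 0.6], [0.5, 0.6]))

    def test_optimal_cutoff_ties_break_toward_preferred(self):
        # any cutoff in [0.70, 0.78] separates perfectly; sweep grid picks 0.78
        cohort = make_cohort([0.60, 0.65, 0.70, 0.79, 0.85, 0.90], [0.7, 0.7, 0.7, 0.9, 0.9, 0.9])
        r = roc_analysis(cohort)
        assert r.optimal_youden == pytest.approx(1.0)
        assert r.optimal_cutoff == pytest.approx(0.78)

    def test_sweep_monotone_in_threshold(self, rng):
        r = roc_analysis(random_cohort(rng, 35))
        # as the cutoff decreases, sensitivity decreases and specificity increases
        assert np.all(np.diff(r.sensitivity) >= 0)
        assert np.all(np.diff(r.specificity) <= 0)


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        x = np.linspace(0, 1, 10)
        assert correlation(x, x)[0] == pytest.approx(1.0)
        assert correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        r, _ = correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        assert r == pytest.approx(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))

    def test_spearman_is_rank_based(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 10.0, 100.0, 1000.0]  # monotone, nonlinear
        assert correlation(x, y, method="spearman")[0] == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_measurements(self):
        a = bland_altman([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert a.mean_diff == 0.0 and a.loa_low == 0.0 and a.loa_high == 0.0

    def test_constant_offset(self):
        x = np.array([0.7, 0.8, 0.9])
        a = bland_altman(x, x + 0.05)
        assert a.mean_diff == pytest.approx(-0.05)
        assert a.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        x, y = rng.random(25), rng.random(25)
        a = bland_altman(x, y)
        d = x - y
        assert a.mean_diff == pytest.approx(d.mean())
        assert a.sd_diff == pytest.approx(d.std(ddof=1))
        assert a.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestCompareMethods:
    def test_identical_cohorts_give_identical_columns(self, rng):
        cohort = random_cohort(rng, 30)
        rep = compare_methods(cohort, cohort, label_a="A", label_b="B")
        assert rep.indices_a == rep.indices_b
        assert rep.roc_a.auc == rep.roc_b.auc
        assert rep.inter_method_corr[0] == pytest.approx(1.0)

    def test_mismatched_ids_raise(self, rng):
        a = random_cohort(rng, 10)
        b = make_cohort(a.index_value, a.invasive_ffr, ids=np.arange(100, 110))
        with pytest.raises(ValueError):
            compare_methods(a, b)

    def test_cells_match_underlying_operations(self, rng):
        a = random_cohort(rng, 30)
        b = make_cohort(
            np.clip(a.invasive_ffr + rng.normal(0, 0.1, 30), 0.25, 1.0), a.invasive_ffr
        )
        rep = compare_methods(a, b, cutoff=0.80)
        assert rep.indices_a == diagnostic_indices(confusion_at_cutoff(a, 0.80))
        assert rep.roc_b.auc == roc_analysis(b).auc
        assert rep.agreement_a == bland_altman(a.index_value, a.invasive_ffr)
        assert rep.corr_b == correlation(b.index_value, b.invasive_ffr)

    def test_markdown_report_has_all_rows(self, rng):
        a = random_cohort(rng, 30)
        b = make_cohort(
            np.clip(a.invasive_ffr + rng.normal(0, 0.1, 30), 0.25, 1.0), a.invasive_ffr
        )
        rep = compare_methods(a, b)
        md = rep.to_markdown()
        for row in ("Accuracy", "Sensitivity", "Specificity", "likelihood ratio", "Youden", "AUC"):
            assert row in md


def trapezoid_auc(cohort):
    """Independent route: trapezoid over the empirical ROC from a threshold sweep."""
    thresholds = np.unique(cohort.index_value)
    truth = cohort.truth_positive
    n1, n0 = truth.sum(), (~truth).sum()
    sens = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = cohort.index_value <= t
        sens.append((pred & truth).sum() / n1)
        fpr.append((pred & ~truth).sum() / n0)
    sens.append(1.0)
    fpr.append(1.0)
    return float(np.trapezoid(sens, fpr))


def test_sweep_trapezoid_auc_equals_mann_whitney(rng):
    """Threshold-sweep (trapezoid) AUC equals the tie-corrected rank AUC."""
    for _ in range(50):
        n = int(rng.integers(6, 50))
        cohort = random_cohort(rng, n)
        assert trapezoid_auc(cohort) == pytest.approx(
            mann_whitney_auc(-cohort.index_value, cohort.truth_positive), abs=1e-12
        )
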