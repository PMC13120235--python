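import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import blendspec as bs
from blendspec.evaluation import _effective_max_lv
from blendspec.io import ValidationError
from blendspec.pls import PLS1Regression
from blendspec.preprocess import apply_pretreatment


def _random_spectra(n, p=20, seed=0, offset=0.0):
    rng = np.random.default_rng(seed)
    grid = 650.0 + 4.0 * np.arange(p)
    return bs.SpectraSet(grid, rng.normal(size=(n, p)) + offset,
                         [f"s{i}" for i in range(n)])


class TestAssignFolds:
    def test_45_samples_10_folds_block_sizes(self):
        folds = bs.assign_folds(45, 10, seed=0)
        sizes = sorted(np.bincount(folds, minlength=10))
        assert sizes == [4] * 5 + [5] * 5

    def test_every_sample_in_exactly_one_fold(self):
        folds = bs.assign_folds(23, 7, seed=1)
        assert folds.size == 23
        assert set(folds) == set(range(7))

    def test_deterministic(self):
        a = bs.assign_folds(30, 10, seed=5)
        b = bs.assign_folds(30, 10, seed=5)
        assert np.array_equal(a, b)

    @given(st.integers(0, 100))
    def test_stratified_positive_balance(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 37, 5
        labels = rng.random(n) < 0.4
        if labels.sum() < 2 or (~labels).sum() < 2:
            return
        folds = bs.assign_folds(n, k, labels, seed=seed)
        pos_counts = [labels[folds == f].sum() for f in range(k)]
        assert max(pos_counts) - min(pos_counts) <= 1
        sizes = sorted(np.bincount(folds, minlength=k))
        assert sizes[-1] - sizes[0] <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            bs.assign_folds(3, 5)


class TestCrossValidate:
    def test_matches_explicit_fold_by_fold_loop(self):
        """The CV engine must equal a hand-written loop that refits the
        pre-treatment and a fresh PLS model per fold and complexity."""
        s = _random_spectra(12, p=8, seed=3)
        rng = np.random.default_rng(4)
        y = rng.normal(size=12) * 10
        spec = bs.PretreatmentSpec("autoscale")
        max_lv = 3
        cv = bs.cross_validate(s, y, spec, max_lv, n_folds=4, seed=9)

        folds = bs.assign_folds(12, 4, None, seed=9)
        assert np.array_equal(folds, cv.fold_assignment)
        for a in range(1, max_lv + 1):
            preds = np.empty(12)
            for f in range(4):
                tr = np.flatnonzero(folds != f)
                te = np.flatnonzero(folds == f)
                tr2, (te2,), _ = apply_pretreatment(
                    spec, s.select(tr), [s.select(te)])
                m = PLS1Regression(n_components=a).fit(tr2.absorbance, y[tr])
                preds[te] = m.predict(te2.absorbance)
            rmse = np.sqrt(np.mean((preds - y) ** 2))
            assert np.isclose(rmse, cv.rmsecv_per_lv[a - 1], atol=1e-8)

    def test_noise_free_linear_relation_has_zero_rmsecv_at_rank(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 5))
        y = X @ rng.normal(size=5) + 2.0
        s = bs.SpectraSet(650.0 + 4.0 * np.arange(5), X,
                          [f"s{i}" for i in range(12)])
        cv = bs.cross_validate(s, y, bs.PretreatmentSpec("autoscale"), 5,
                               n_folds=4, seed=0)
        assert cv.rmsecv_per_lv[-1] < 1e-8

    def test_rmsecv_vector_length(self):
        s = _random_spectra(20, p=10, seed=7)
        y = np.random.default_rng(8).normal(size=20)
        cv = bs.cross_validate(s, y, bs.PretreatmentSpec("snv"), 4,
                               n_folds=5, seed=0)
        assert cv.rmsecv_per_lv.size == 4
        assert cv.cv_predictions.shape == (20, 4)

    def test_classification_reports_ccr_per_lv(self):
        s = _random_spectra(20, p=10, seed=9)
        s.absorbance[:10] += 3.0  # separable classes
        y = (np.arange(20) < 10).astype(float)
        cv = bs.cross_validate(s, y, bs.PretreatmentSpec("autoscale"), 3,
                               n_folds=5, seed=0, task="classification")
        assert cv.ccr_per_lv is not None and cv.ccr_per_lv.size == 3
        assert cv.ccr_per_lv.max() == 100.0


class TestSelectNLatent:
    @pytest.mark.parametrize(
        "rmsecv, expected",
        [((3.0, 2.0, 2.0, 4.0), 2),
         ((5.0, 4.0, 3.0, 2.0), 4),
         ((1.0, 1.0, 1.0), 1)],
    )
    def test_argmin_with_parsimony_tie_rule(self, rmsecv, expected):
        assert bs.select_n_latent(np.array(rmsecv)) == expected

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            bs.select_n_latent(np.array([]))


class TestClassificationMetrics:
    def test_40_of_45_correct(self):
        y_true = np.repeat([True, False], [22, 23])
        y_pred = y_true.copy()
        y_pred[:2] = False  # 2 false negatives
        y_pred[22:25] = True  # 3 false positives
        m = bs.classification_metrics(y_true, y_pred)
        assert round(m.ccr, 2) == 88.89

    def test_confusion_20_2_3_20(self):
        y_true = np.repeat([True, False], [22, 23])
        y_pred = np.concatenate([
            np.repeat([True, False], [20, 2]),
            np.repeat([True, False], [3, 20]),
        ])
        m = bs.classification_metrics(y_true, y_pred)
        assert (m.tp, m.fn, m.fp, m.tn) == (20, 2, 3, 20)
        assert round(m.sensitivity, 2) == 0.91
        assert round(m.specificity, 2) == 0.87
        assert round(m.precision, 2) == 0.87

    def test_all_correct(self):
        y = np.array([True, False, True])
        m = bs.classification_metrics(y, y)
        assert m.ccr == 100.0
        assert m.precision == m.specificity == m.sensitivity == 1.0

    def test_undefined_ratio_is_nan_with_warning(self):
        y_true = np.array([False, False])
        y_pred = np.array([False, False])
        with pytest.warns(UserWarning, match="undefined"):
            m = bs.classification_metrics(y_true, y_pred)
        assert math.isnan(m.precision) and math.isnan(m.sensitivity)

    @given(st.integers(0, 500))
    def test_label_swap_exchanges_sensitivity_and_specificity(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.random(30) < 0.5
        y_pred = rng.random(30) < 0.5
        if y_true.all() or not y_true.any():
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = bs.classification_metrics(y_true, y_pred)
            b = bs.classification_metrics(~y_true, ~y_pred)
        assert a.sensitivity == b.specificity or (
            math.isnan(a.sensitivity) and math.isnan(b.specificity))
        assert a.ccr == b.ccr

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        y_true = rng.random(20) < 0.5
        y_pred = rng.random(20) < 0.5
        perm = rng.permutation(20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert bs.classification_metrics(y_true, y_pred) == \
                bs.classification_metrics(y_true[perm], y_pred[perm])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bs.classification_metrics([True], [True, False])


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 5.0, 9.0])
        m = bs.regression_metrics(y, y)
        assert m.rmsep == 0.0 and m.r2p == 1.0
        assert math.isinf(m.rpd) and math.isinf(m.rer)
        assert m.rpd_band == "excellent" and m.rer_band == "excellent"

    def test_rpd_one_when_sd_equals_rmsep(self):
        y_true = np.array([-1.0, 1.0])  # SD (n-1) = sqrt(2)
        y_pred = y_true + np.sqrt(2.0)
        m = bs.regression_metrics(y_true, y_pred)
        assert np.isclose(m.rpd, 1.0)

    def test_hand_example(self):
        m = bs.regression_metrics([0.0, 50.0, 100.0], [10.0, 50.0, 90.0])
        assert np.isclose(m.rmsep, math.sqrt(200.0 / 3.0))
        assert np.isclose(m.rer, 100.0 / math.sqrt(200.0 / 3.0))
        assert np.isclose(m.rer, 12.247, atol=1e-3)

    @given(st.integers(0, 500))
    def test_rpd_rer_definitions(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.normal(size=10) * 30
        y_pred = y_true + rng.normal(size=10)
        m = bs.regression_metrics(y_true, y_pred)
        assert np.isclose(m.rpd * m.rmsep, np.std(y_true, ddof=1), atol=1e-10)
        assert np.isclose(m.rer * m.rmsep, np.ptp(y_true), atol=1e-10)

    def test_interpretation_bands(self):
        from blendspec.evaluation import _rer_band, _rpd_band
        assert [_rpd_band(x) for x in (1.0, 1.7, 2.2, 2.7, 3.5)] == [
            "poor", "rough screening", "approximate", "good", "excellent"]
        assert [_rer_band(x) for x in (3.0, 7.0, 11.0)] == [
            "poor", "acceptable", "excellent"]

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValidationError):
            bs.regression_metrics([5.0, 5.0], [4.0, 6.0])


@pytest.fixture(scope="module")
def small_problem():
    cfg = bs.GeneratorConfig(seed=2, noise_sigma=0.002)
    em = bs.generate_endmembers(cfg)
    design = bs.build_mixture_design()
    s, comp = bs.synthesize_spectra(design, em, cfg)
    y = comp.proportion_of("RT2")
    split = bs.duplex_split(s.absorbance, 13)
    return (s.select(split.train_indices), s.select(split.test_indices),
            y[split.train_indices], y[split.test_indices])


class TestSweep:
    def test_report_structure_and_chosen_minimises_rmsep(self, small_problem):
        tr, te, ytr, yte = small_problem
        rep = bs.sweep_pretreatments(tr, te, ytr, yte, task="regression",
                                     max_lv=8, seed=0)
        assert len(rep.table) == 6
        assert set(rep.table["pretreatment"]) == set(bs.PRETREATMENTS)
        for col in ("n_lv", "rmsep", "rmsecv", "r2p", "r2cv", "rpd", "rer"):
            assert col in rep.table.columns
        chosen_rmsep = rep.table.set_index("pretreatment").loc[rep.chosen, "rmsep"]
        assert round(chosen_rmsep, 4) == round(rep.table["rmsep"].min(), 4)

    def test_classification_tie_broken_by_cv(self, small_problem):
        tr, te, ytr, yte = small_problem
        rep = bs.sweep_pretreatments(tr, te, (ytr > 0).astype(float),
                                     (yte > 0).astype(float),
                                     task="classification", max_lv=8, seed=0)
        t = rep.table.set_index("pretreatment")
        best_test = round(t["ccr_test"].max(), 4)
        tied = t[t["ccr_test"].round(4) == best_test]
        assert round(t.loc[rep.chosen, "ccr_test"], 4) == best_test
        assert round(t.loc[rep.chosen, "ccr_cv"], 4) == round(
            tied["ccr_cv"].max(), 4)

    def test_cv_untouched_by_test_set_mutation(self, small_problem):
        tr, te, ytr, yte = small_problem
        rep_a = bs.sweep_pretreatments(tr, te, ytr, yte, task="regression",
                                       max_lv=5, seed=0)
        te_bad = bs.SpectraSet(te.grid, te.absorbance * 50.0 + 1.0,
                               te.sample_ids)
        rep_b = bs.sweep_pretreatments(tr, te_bad, ytr, yte, task="regression",
                                       max_lv=5, seed=0)
        assert np.array_equal(rep_a.table["rmsecv"], rep_b.table["rmsecv"])
        assert np.array_equal(rep_a.table["n_lv"], rep_b.table["n_lv"])

    def test_overlapping_sets_rejected(self, small_problem):
        tr, te, ytr, yte = small_problem
        with pytest.raises(ValidationError, match="overlap"):
            bs.sweep_pretreatments(tr, tr, ytr, ytr, task="regression")

    def test_effective_max_lv_cap(self):
        # n_train = 45, 10 folds: cap at 45 - ceil(45/10) - 1 = 39
        assert _effective_max_lv(15, 45, 10) == 15
        assert _effective_max_lv(50, 45, 10) == 39
        assert _effective_max_lv(15, 12, 4) == 8


class TestLOD:
    class _StubModel:
        def __init__(self, flags):
            self.flags = np.asarray(flags, dtype=bool)

        def predict(self, X):
            return self.flags

    def _series(self, n=4):
        grid = 650.0 + 4.0 * np.arange(5)
        return bs.SpectraSet(grid, np.ones((n, 5)) * np.arange(n)[:, None],
                             [f"t{i}" for i in range(n)])

    def test_all_positive_gives_lowest_level(self):
        r = bs.estimate_lod(self._StubModel([1, 1, 1, 1]), None,
                            self._series(), [1, 2, 5, 8], "RT2")
        assert r.lod == 1.0 and r.label == "1%"

    def test_none_positive_marks_above_range(self):
        r = bs.estimate_lod(self._StubModel([0, 0, 0, 0]), None,
                            self._series(), [1, 2, 5, 8])
        assert r.lod is None and r.label == ">8%"

    def test_monotone_tail_rule_ignores_isolated_positive(self):
        r = bs.estimate_lod(self._StubModel([1, 0, 1, 1]), None,
                            self._series(), [1, 2, 5, 8])
        assert r.lod == 5.0
        assert r.positive_flags == (True, False, True, True)

    def test_unsorted_levels_rejected(self):
        with pytest.raises(ValidationError):
            bs.estimate_lod(self._StubModel([1, 1]), None, self._series(2),
                            [5, 2])
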