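import types

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from pzrad import (
    ROIMask,
    RunConfig,
    SvmHyperparams,
    bayes_optimize,
    cfs_merit,
    cfs_search,
    compute_metrics,
    curate_reference_labels,
    dice,
    lopo_run,
    platt_calibrate,
    platt_probability,
    train_rbf_svm,
)
from pzrad.model import CalibrationError, LabelingError
from pzrad.volume_io import GridMismatchError

SP = (1.0, 1.0, 1.0)


def _matrix(X, y, patient="p0"):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df.insert(0, "label", y)
    df.insert(0, "patient_id", patient)
    return df


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

class TestCfsMerit:
    def test_single_feature_collapses_to_class_correlation(self):
        assert cfs_merit(1, 0.63, 0.9) == pytest.approx(0.63)

    def test_two_feature_example(self):
        assert cfs_merit(2, 0.8, 0.5) == pytest.approx(1.6 / np.sqrt(3.0))

    def test_duplicate_feature_never_increases_merit(self):
        """Adding an exact copy (corr 1 with its twin) cannot raise merit."""
        rcf = 0.7
        for k in range(1, 6):
            base = cfs_merit(k, rcf, 0.3)
            # duplicating one feature: class corr unchanged, the new pairwise
            # correlations include a 1.0 for the twin and 0.3 elsewhere
            n_pairs = k * (k + 1) // 2
            new_rff = (0.3 * (n_pairs - 1) + 1.0) / n_pairs
            assert cfs_merit(k + 1, rcf, new_rff) <= base + 1e-12

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            cfs_merit(2, 1.5, 0.2)


class TestCfsSearch:
    def test_informative_feature_selected(self, rng):
        y = np.repeat([1, -1], 100)
        X = rng.normal(size=(200, 6))
        X[:, 2] = y + rng.normal(0, 0.05, 200)
        res = cfs_search(_matrix(X, y))
        assert "f2" in res.selected

    def test_duplicate_informative_feature_selected_once(self, rng):
        y = np.repeat([1, -1], 100)
        signal = y + rng.normal(0, 0.05, 200)
        X = rng.normal(size=(200, 5))
        X[:, 1] = signal
        X[:, 3] = signal
        res = cfs_search(_matrix(X, y))
        assert len({"f1", "f3"} & set(res.selected)) == 1

    def test_all_noise_low_merit_bounded_selection(self, rng):
        # pure-noise correlations are O(1/sqrt(n)); merit stays near 0 and
        # the best-first search stalls long before exhausting the pool
        y = np.repeat([1, -1], 100)
        X = rng.normal(size=(200, 10))
        res = cfs_search(_matrix(X, y))
        assert res.merit < 0.25
        assert len(res.selected) < 10

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 4))
        with pytest.raises(LabelingError):
            cfs_search(_matrix(X, np.ones(50)))

    def test_selected_subset_dominates_singletons(self, rng):
        y = np.repeat([1, -1], 80)
        X = rng.normal(size=(160, 8))
        X[:, 0] = y + rng.normal(0, 0.3, 160)
        X[:, 5] = y + rng.normal(0, 0.5, 160)
        res = cfs_search(_matrix(X, y))
        cols = [f"f{i}" for i in range(8)]
        df = _matrix(X, y)
        singles = [
            abs(np.corrcoef(df[c], y)[0, 1]) for c in cols
        ]
        assert res.merit >= max(singles) - 1e-12


# ---------------------------------------------------------------------------
# SVM training
# ---------------------------------------------------------------------------

class TestRbfSvm:
    def test_separable_blobs_high_training_accuracy(self, rng):
        y = np.repeat([1, -1], 50)
        X = rng.normal(0, 0.15, (100, 2))
        X[y == 1] += (0.8, 0.8)
        df = _matrix(X, y)
        svc = train_rbf_svm(df, SvmHyperparams(1.0, 1.0))
        acc = (svc.predict(X) == y).mean()
        assert acc >= 0.99

    def test_xor_pattern_needs_nonlinearity(self, rng):
        n = 200
        X = rng.uniform(0, 1, (n, 2))
        y = np.where((X[:, 0] > 0.5) ^ (X[:, 1] > 0.5), 1, -1)
        svc = train_rbf_svm(_matrix(X, y), SvmHyperparams(10.0, 10.0))
        assert (svc.predict(X) == y).mean() > 0.9
        # any linear separator is near chance on XOR
        from sklearn.svm import LinearSVC

        lin = LinearSVC(C=10.0).fit(X, y)
        assert (lin.predict(X) == y).mean() < 0.7

    def test_duplicated_training_set_same_boundary(self, rng):
        # holds in the separable regime (no active slack): the duplicated
        # support vectors reproduce the same stationary solution
        y = np.repeat([1, -1], 40)
        X = rng.normal(0, 0.2, (80, 2))
        X[y == 1] += (2.0, 2.0)
        df1 = _matrix(X, y)
        df2 = _matrix(np.vstack([X, X]), np.concatenate([y, y]))
        hp = SvmHyperparams(5.0, 2.0)
        m1, m2 = train_rbf_svm(df1, hp), train_rbf_svm(df2, hp)
        probe = rng.uniform(-0.5, 1.5, (50, 2))
        np.testing.assert_allclose(
            m1.decision_function(probe), m2.decision_function(probe), atol=1e-6
        )

    def test_single_class_rejected(self, rng):
        with pytest.raises(LabelingError):
            train_rbf_svm(
                _matrix(rng.normal(size=(20, 2)), np.ones(20)),
                SvmHyperparams(1.0, 1.0),
            )


class TestBayesOptimize:
    @pytest.fixture(scope="class")
    def blob_matrix(self):
        rng = np.random.default_rng(7)
        y = np.tile([1, -1], 60)
        X = rng.normal(0, 0.4, (120, 3))
        X[y == 1] += 0.9
        df = _matrix(np.clip(X, -2, 3), y)
        df["patient_id"] = np.repeat([f"p{i}" for i in range(6)], 20)
        return df

    def test_incumbent_within_bounds(self, blob_matrix):
        hp = bayes_optimize(blob_matrix, folds=4, iterations=10, seed=3)
        assert 1e-4 <= hp.C <= 1e3 and 1e-4 <= hp.gamma <= 1e3

    def test_deterministic_under_seed(self, blob_matrix):
        a = bayes_optimize(blob_matrix, folds=4, iterations=8, seed=11)
        b = bayes_optimize(blob_matrix, folds=4, iterations=8, seed=11)
        assert (a.C, a.gamma) == (b.C, b.gamma)

    def test_beats_fixed_default_on_cv_auroc(self, blob_matrix):
        from sklearn.metrics import roc_auc_score
        from sklearn.svm import SVC

        from pzrad.model import _cv_splits

        hp = bayes_optimize(blob_matrix, folds=4, iterations=12, seed=5)
        y = blob_matrix["label"].to_numpy()
        X = blob_matrix[[c for c in blob_matrix if c.startswith("f")]].to_numpy()
        splits = _cv_splits(y, blob_matrix["patient_id"].to_numpy(), 4, 5)

        def cv_auc(C, gamma):
            aucs = []
            for tr, va in splits:
                svc = SVC(C=C, gamma=gamma, class_weight="balanced").fit(X[tr], y[tr])
                aucs.append(roc_auc_score(y[va] == 1, svc.decision_function(X[va])))
            return np.mean(aucs)

        assert cv_auc(hp.C, hp.gamma) >= cv_auc(1.0, 1.0) - 1e-9

    def test_too_many_folds_rejected(self, rng):
        y = np.array([1] * 3 + [-1] * 30)
        df = _matrix(rng.normal(size=(33, 2)), y)
        from pzrad.model import StratificationError

        with pytest.raises(StratificationError):
            bayes_optimize(df, folds=10, iterations=5, seed=0)


# ---------------------------------------------------------------------------
# Platt calibration
# ---------------------------------------------------------------------------

class TestPlatt:
    def test_zero_parameters_give_half(self):
        np.testing.assert_allclose(
            platt_probability([-3.0, 0.0, 5.0], 0.0, 0.0), 0.5
        )

    def test_symmetric_balanced_case_matches_independent_minimizer(self):
        f = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = np.concatenate([np.full(20, -1), np.full(20, 1)])
        A, B = platt_calibrate(f, y)
        assert A < 0
        assert platt_probability(0.0, A, B) == pytest.approx(0.5, abs=1e-6)

        # independent oracle: scipy minimization of the same regularized NLL
        t = np.where(y > 0, 21.0 / 22.0, 1.0 / 22.0)

        def nll(params):
            a, b = params
            z = f * a + b
            # -sum t log p + (1-t) log(1-p) with p = 1/(1+exp(z))
            return np.sum(t * z + np.logaddexp(0.0, -z))

        res = minimize(nll, x0=(0.0, 0.0), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert A == pytest.approx(res.x[0], abs=1e-4)
        assert B == pytest.approx(res.x[1], abs=1e-4)

    def test_label_flip_symmetry(self, rng):
        f = rng.normal(size=60)
        y = np.where(rng.random(60) > 0.4, 1, -1)
        A1, B1 = platt_calibrate(f, y)
        A2, B2 = platt_calibrate(-f, -y)
        assert A2 == pytest.approx(A1, abs=1e-6)
        assert B2 == pytest.approx(-B1, abs=1e-6)

    def test_monotone_in_decision_value(self, rng):
        f = rng.normal(size=80)
        y = np.where(f + rng.normal(0, 0.5, 80) > 0, 1, -1)
        A, B = platt_calibrate(f, y)
        probe = np.linspace(-3, 3, 50)
        p = platt_probability(probe, A, B)
        assert np.all(np.diff(p) > 0)

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            platt_calibrate([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------------------
# Metrics, Dice, label curation
# ---------------------------------------------------------------------------

class TestMetrics:
    def test_perfect_and_reversed_ordering(self):
        y = [1, 1, -1, -1]
        assert compute_metrics([4, 3, 2, 1], y)["auroc"] == 1.0
        assert compute_metrics([1, 2, 3, 4], y)["auroc"] == 0.0

    def test_pair_counting_example(self):
        # labels (+,-,+,-) on scores (.9,.8,.4,.3): 3 of 4 pairs ordered
        m = compute_metrics([0.9, 0.8, 0.4, 0.3], [1, -1, 1, -1])
        assert m["auroc"] == pytest.approx(0.75)

    def test_auroc_matches_pair_counting_oracle(self, rng):
        scores = rng.normal(size=100)
        y = np.where(rng.random(100) > 0.6, 1, -1)
        pos, neg = scores[y > 0], scores[y < 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = wins / (len(pos) * len(neg))
        assert compute_metrics(scores, y)["auroc"] == pytest.approx(expected)

    def test_invariant_under_monotone_transforms(self, rng):
        scores = rng.normal(size=60)
        y = np.where(rng.random(60) > 0.5, 1, -1)
        base = compute_metrics(scores, y)["auroc"]
        for fn in (np.exp, lambda s: 3 * s + 7, np.tanh):
            assert compute_metrics(fn(scores), y)["auroc"] == pytest.approx(base)

    def test_thresholded_binary_metrics(self):
        m = compute_metrics([2.0, 1.0, -1.0, -2.0], [1, -1, 1, -1])
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 0.5
        assert m["accuracy"] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(LabelingError):
            compute_metrics([1.0, 2.0], [1, 1])


class TestDice:
    def _mask(self, cells, shape=(1, 4, 4)):
        data = np.zeros(shape, bool)
        for s, r, c in cells:
            data[s, r, c] = True
        return ROIMask(data, SP)

    def test_identity(self):
        m = self._mask([(0, 0, 0), (0, 1, 1)])
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        assert dice(self._mask([(0, 0, 0)]), self._mask([(0, 3, 3)])) == 0.0

    def test_half_overlap(self):
        a = self._mask([(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 0, 3)])
        b = self._mask([(0, 0, 2), (0, 0, 3), (0, 1, 0), (0, 1, 1)])
        assert dice(a, b) == 0.5

    def test_both_empty_defined_one(self):
        assert dice(self._mask([]), self._mask([])) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            dice(self._mask([]), self._mask([], shape=(1, 5, 5)))


class TestCurateLabels:
    def _pz(self, shape=(2, 10, 10), spacing=SP):
        return ROIMask(np.ones(shape, bool), spacing, "PZ")

    def _lesion(self, rows, cols, shape=(2, 10, 10), spacing=SP, label="rater1"):
        data = np.zeros(shape, bool)
        data[:, rows[0]:rows[1], cols[0]:cols[1]] = True
        return ROIMask(data, spacing, label)

    def test_identical_raters_keep_mask(self):
        r1 = self._lesion((2, 5), (2, 5))
        r2 = self._lesion((2, 5), (2, 5), label="rater2")
        cancer, noncancer, excl = curate_reference_labels([r1], [r2], self._pz())
        assert excl == []
        np.testing.assert_array_equal(cancer.data, r1.data)
        assert not (cancer.data & noncancer.data).any()

    def test_disjoint_subthreshold_lesions_excluded(self):
        # 0.2 cc at 10 mm^3/voxel = 20 voxels each, no overlap
        spacing = (2.5, 2.0, 2.0)
        shape = (2, 10, 10)
        r1 = ROIMask(np.zeros(shape, bool), spacing, "rater1")
        r1.data[0, 0:4, 0:5] = True
        r2 = ROIMask(np.zeros(shape, bool), spacing, "rater2")
        r2.data[1, 6:10, 5:10] = True
        assert r1.volume_cc == pytest.approx(0.2)
        pz = ROIMask(np.ones(shape, bool), spacing, "PZ")
        cancer, _, excl = curate_reference_labels([r1], [r2], pz)
        assert cancer.voxel_count == 0
        assert len(excl) == 2
        assert all(e["sub_threshold"] for e in excl)

    def test_partial_overlap_keeps_intersection(self):
        r1 = self._lesion((2, 6), (2, 6))
        r2 = self._lesion((4, 8), (4, 8), label="rater2")
        cancer, noncancer, excl = curate_reference_labels([r1], [r2], self._pz())
        np.testing.assert_array_equal(cancer.data, r1.data & r2.data)
        # the discordant ring belongs to noncancer
        ring = (r1.data | r2.data) & ~(r1.data & r2.data)
        assert np.all(noncancer.data[ring])

    def test_cancer_clipped_to_pz_with_warning(self):
        pz = ROIMask(np.zeros((2, 10, 10), bool), SP, "PZ")
        pz.data[:, 0:5, :] = True
        r1 = self._lesion((3, 7), (2, 5))
        r2 = self._lesion((3, 7), (2, 5), label="rater2")
        with pytest.warns(UserWarning, match="clipped"):
            cancer, _, _ = curate_reference_labels([r1], [r2], pz)
        assert not (cancer.data & ~pz.data).any()


# ---------------------------------------------------------------------------
# LOPO bookkeeping on synthetic matrices
# ---------------------------------------------------------------------------

def _synthetic_cohort_matrices(rng, n_patients=4, n_rows=70, informative=True):
    cases, matrices = [], {}
    for i in range(n_patients):
        pid = f"p{i}"
        y = np.where(rng.random(n_rows) > 0.75, 1, -1)
        X = rng.normal(size=(n_rows, 5))
        if informative:
            X[:, 0] += 1.5 * y
        df = _matrix(X, y, patient=pid)
        df.insert(2, "slice", 0)
        df.insert(3, "row", np.arange(n_rows))
        df.insert(4, "col", 0)
        cases.append(types.SimpleNamespace(patient_id=pid))
        matrices[pid] = df
    return cases, matrices


FAST_CFG = RunConfig(bo_iterations=6, bo_folds=3, max_train_voxels=300, seed=5)


class TestLopo:
    def test_fold_bookkeeping_excludes_held_out_patient(self, rng):
        cases, matrices = _synthetic_cohort_matrices(rng)
        report, models = lopo_run(cases, FAST_CFG, matrices=matrices)
        assert len(report.per_fold) == 4
        for rec in report.per_fold:
            assert rec["patient_id"] not in rec["train_patient_ids"]
            assert len(rec["train_patient_ids"]) == 3

    def test_informative_data_beats_chance(self, rng):
        cases, matrices = _synthetic_cohort_matrices(rng)
        report, _ = lopo_run(cases, FAST_CFG, matrices=matrices)
        assert report.aggregate["auroc"]["mean"] > 0.8

    def test_deterministic_given_seed(self, rng):
        cases, matrices = _synthetic_cohort_matrices(rng)
        r1, _ = lopo_run(cases, FAST_CFG, matrices=matrices)
        r2, _ = lopo_run(cases, FAST_CFG, matrices=matrices)
        assert r1.aggregate == r2.aggregate

    def test_too_few_patients_rejected(self, rng):
        cases, matrices = _synthetic_cohort_matrices(rng, n_patients=2)
        with pytest.raises(ValueError):
            lopo_run(cases, FAST_CFG, matrices=matrices)
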