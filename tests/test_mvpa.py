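"""Between-subject decoding: LOSO SVM, permutation nulls, sensitivity maps,
median-split construction, per-modality balancing and cross-dataset
generalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVC

from painpattern import (Mask, SampleSet, SensitivityMap,
                         balance_classes_by_modality, consistent_sign_map,
                         cross_dataset_classify, loso_classify,
                         median_split_classes, permutation_null,
                         pooled_median_split_average, sensitivity_map)
from painpattern.mvpa import _fit_gram, _p_from_null, _predict_gram
from painpattern.preprocess import PatternSample


def make_set(X, y, subjects, positive="pain", normalized=False):
    return SampleSet(X=np.asarray(X, float), y=np.asarray(y),
                     subjects=np.asarray(subjects), positive_class=positive,
                     normalized=normalized)


def paired_noise_set(rng, n_sub=8, n_vox=20, shift=0.0, normalized=False):
    X, y, subs = [], [], []
    for s in range(n_sub):
        X.append(rng.normal(size=n_vox) + shift)
        y.append("pain")
        subs.append(f"s{s}")
        X.append(rng.normal(size=n_vox))
        y.append("touch")
        subs.append(f"s{s}")
    return make_set(np.vstack(X), y, subs, normalized=normalized)


def svm_qp_reference(X, y, C=1.0):
    """Independent soft-margin SVM: solve the dual QP with SLSQP and recover
    (w, b) from the KKT conditions."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    cons = [{"type": "eq", "fun": lambda a: a @ y}]
    res = minimize(neg_dual, np.full(n, C / 2), jac=lambda a: Q @ a - 1,
                   bounds=[(0.0, C)] * n, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    a = res.x
    w = (a * y) @ X
    margin = (a > 1e-6) & (a < C - 1e-6)
    if margin.any():
        b = float(np.mean(y[margin] - X[margin] @ w))
    else:  # fall back to the KKT interval midpoint
        up = y * (X @ w)
        lo_set = up[(y == 1) & (a < C - 1e-6)] if ((y == 1) & (a < C - 1e-6)).any() else None
        b_candidates = y - X @ w
        b = float(np.median(b_candidates[a > 1e-6]))
    return w, b


class TestLosoClassify:
    def test_perfectly_separable_1d(self):
        X = np.array([[1.0], [-1.0]] * 10)
        y = ["pain", "touch"] * 10
        subs = np.repeat([f"s{i}" for i in range(10)], 2)
        res = loso_classify(make_set(X, y, subs))
        assert res.accuracy == 1.0
        assert np.all(res.fold_accuracies == 1.0)
        assert res.weights[0] > 0  # pain side is positive

    def test_fold_structure(self, rng):
        sset = paired_noise_set(rng, n_sub=6)
        res = loso_classify(sset)
        assert len(res.fold_accuracies) == 6
        assert res.accuracy == pytest.approx(res.fold_accuracies.mean())
        assert res.fold_weights.shape == (6, 20)

    def test_single_class_training_rejected(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError):
            loso_classify(make_set(X, ["pain"] * 4, ["a", "a", "b", "b"]))

    def test_two_subject_warning(self, rng):
        sset = paired_noise_set(rng, n_sub=2)
        with pytest.warns(UserWarning, match="2 subjects"):
            loso_classify(sset)

    def test_voxel_permutation_invariance(self, rng):
        sset = paired_noise_set(rng, n_sub=6, shift=0.5)
        perm = rng.permutation(sset.X.shape[1])
        shuffled = make_set(sset.X[:, perm], sset.y, sset.subjects)
        a = loso_classify(sset)
        b = loso_classify(shuffled)
        assert a.accuracy == b.accuracy
        assert [p.tolist() for p in a.fold_predictions] == \
            [p.tolist() for p in b.fold_predictions]

    def test_fast_gram_path_matches_sklearn_svc(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 24))
            X = rng.normal(size=(n, 10))
            y = rng.choice([-1, 1], n)
            if len(set(y)) < 2:
                continue
            G = X @ X.T
            ours = _fit_gram(G, y, C=1.0)
            ref = SVC(kernel="precomputed", C=1.0).fit(G, y)
            Gt = rng.normal(size=(5, n))
            assert np.array_equal(_predict_gram(ours, Gt), ref.predict(Gt))
            assert np.allclose(
                ours.dual_coef_[0] @ X[ours.support_],
                ref.dual_coef_[0] @ X[ref.support_])

    def test_fold_predictions_match_qp_reference(self, rng):
        # tiny instances: LOSO folds vs an independent quadratic program
        for trial in range(10):
            n_sub = 4
            X = rng.normal(size=(2 * n_sub, 3)) + \
                np.tile([[1.0, 0, 0], [-1.0, 0, 0]], (n_sub, 1))
            y = np.array(["pain", "touch"] * n_sub)
            subs = np.repeat([f"s{i}" for i in range(n_sub)], 2)
            sset = make_set(X, y, subs)
            res = loso_classify(sset)
            for f, s in enumerate(res.fold_subjects):
                tr = subs != s
                w, b = svm_qp_reference(X[tr], np.where(y[tr] == "pain", 1, -1))
                d = X[~tr] @ w + b
                assert np.all(np.abs(d) > 1e-6), "ambiguous reference decision"
                expected = np.where(d > 0, 1, -1)
                assert np.array_equal(res.fold_predictions[f], expected)


class TestPermutationNull:
    def test_p_value_counting_rules(self):
        assert _p_from_null(np.array([0.4, 0.5, 0.6]), 0.55) == \
            (pytest.approx(1 / 3), False)
        assert _p_from_null(np.array([0.4, 0.5, 0.6]), 0.4) == (1.0, False)
        p, floored = _p_from_null(np.full(5000, 0.5), 0.9)
        assert p == 0.0002 and floored

    def test_plus_one_estimator(self):
        p, floored = _p_from_null(np.full(99, 0.4), 0.9, estimator="plus_one")
        assert p == pytest.approx(1 / 100) and not floored

    def test_determinism(self, rng):
        sset = paired_noise_set(rng, n_sub=5, shift=0.8)
        a = permutation_null(sset, n_perm=50, seed=9)
        b = permutation_null(sset, n_perm=50, seed=9)
        assert np.array_equal(a.null_accuracies, b.null_accuracies)
        assert a.p_value == b.p_value

    def test_strong_signal_hits_floor(self, rng):
        X = np.vstack([np.tile([5.0, 0, 0], (8, 1)) + rng.normal(0, .1, (8, 3)),
                       np.tile([-5.0, 0, 0], (8, 1)) + rng.normal(0, .1, (8, 3))])
        order = np.arange(16).reshape(2, 8).T.ravel()
        y = np.array(["pain"] * 8 + ["touch"] * 8)[order]
        subs = np.repeat([f"s{i}" for i in range(8)], 2)
        sset = make_set(X[order], y, subs)
        res = permutation_null(sset, n_perm=100, seed=1)
        assert res.accuracy == 1.0
        assert res.p_is_floor and res.p_value == pytest.approx(1 / 100)
        assert res.p_report == "< 0.01"

    def test_null_centered_at_chance(self, rng):
        sset = paired_noise_set(rng, n_sub=8)
        res = permutation_null(sset, n_perm=300, seed=4)
        assert abs(res.null_accuracies.mean() - 0.5) < 0.05


class TestSensitivityMaps:
    def _mask(self, n=8):
        data = np.zeros((2, 2, 2), dtype=bool).ravel()
        data[:n] = True
        return Mask(data.reshape(2, 2, 2))

    def test_identical_folds_give_that_weight(self, rng):
        sset = paired_noise_set(rng, n_sub=4, n_vox=8)
        res = loso_classify(sset)
        res.fold_weights = np.tile(np.arange(8.0), (4, 1))
        m = sensitivity_map(res, self._mask())
        assert np.allclose(m.values, np.arange(8.0))

    def test_label_flip_flips_weights(self, rng):
        sset = paired_noise_set(rng, n_sub=6, n_vox=8, shift=1.0)
        res = loso_classify(sset)
        flipped = make_set(sset.X, sset.y, sset.subjects, positive="touch")
        res_f = loso_classify(flipped)
        # naming the other class positive flips every weight sign (up to
        # libsvm's solver tolerance)
        assert np.allclose(res_f.weights, -res.weights, atol=1e-3)
        # sign semantics: the pain-shifted voxels carry positive weight under
        # the pain-positive convention
        m = sensitivity_map(res, self._mask())
        assert m.values.mean() > 0

    def test_length_mismatch_rejected(self, rng):
        sset = paired_noise_set(rng, n_sub=4, n_vox=5)
        res = loso_classify(sset)
        with pytest.raises(ValueError):
            sensitivity_map(res, self._mask(8))

    def test_consistent_sign_rules(self):
        mask = self._mask(2)
        a = SensitivityMap(np.array([1.0, 1.0]), mask)
        b = SensitivityMap(np.array([-1.0, 3.0]), mask)
        out = consistent_sign_map([a, b])
        assert out.values[0] == 0.0
        assert out.values[1] == pytest.approx(2.0)

    def test_consistent_sign_random_oracle(self, rng):
        mask = self._mask(8)
        maps = [SensitivityMap(rng.normal(size=8), mask) for _ in range(3)]
        out = consistent_sign_map(maps)
        V = np.vstack([m.values for m in maps])
        for v in range(8):
            same = np.all(np.sign(V[:, v]) == np.sign(V[0, v])) and V[0, v] != 0
            if same:
                assert out.values[v] == pytest.approx(V[:, v].mean())
            else:
                assert out.values[v] == 0.0


def trial_sample(rating, modality, subject, values=None, rng=None):
    v = values if values is not None else rng.normal(size=4)
    return PatternSample(v, meta={"rating": rating, "modality": modality,
                                  "subject": subject})


class TestMedianSplit:
    def test_even_split_of_sequential_ratings(self, rng):
        samples = [trial_sample(float(r), "pain", f"s{r % 14}", rng=rng)
                   for r in range(1, 57)]
        sset = median_split_classes(samples)
        assert (sset.y == "high").sum() == 28
        assert (sset.y == "low").sum() == 28

    def test_ties_go_low(self, rng):
        ratings = [1.0, 2.0, 2.0, 3.0]  # median 2.0: ties assigned low
        samples = [trial_sample(r, "pain", f"s{i}", rng=rng)
                   for i, r in enumerate(ratings)]
        sset = median_split_classes(samples)
        assert (sset.y == "low").sum() == 3
        assert (sset.y == "high").sum() == 1

    def test_degenerate_ratings_rejected(self, rng):
        samples = [trial_sample(5.0, "pain", f"s{i}", rng=rng)
                   for i in range(4)]
        with pytest.raises(ValueError, match="degenerate"):
            median_split_classes(samples)


class TestBalanceByModality:
    def build_split_set(self, high_counts, low_counts, rng):
        samples = []
        i = 0
        for mod, k in high_counts.items():
            for j in range(k):
                s = trial_sample(6.0 + j, mod, f"s{i}", rng=rng)
                s.meta["class"] = "high"
                samples.append(s)
                i += 1
        for mod, k in low_counts.items():
            for j in range(k):
                s = trial_sample(4.0 - j, mod, f"s{i}", rng=rng)
                s.meta["class"] = "low"
                samples.append(s)
                i += 1
        return SampleSet.from_samples(samples, class_key="class",
                                      positive_class="high",
                                      keep=("modality", "rating", "class"))

    def test_published_counts_worked_example(self, rng):
        high = {"pain": 10, "touch": 6, "audition": 7, "vision": 5}
        low = {"pain": 4, "touch": 8, "audition": 7, "vision": 9}
        sset = self.build_split_set(high, low, rng)
        out = balance_classes_by_modality(sset)
        assert out.n_samples == 44
        y = out.y.astype(str)
        assert (y == "high").sum() == 22 and (y == "low").sum() == 22
        for mod, k in {"pain": 4, "touch": 6, "audition": 7, "vision": 5}.items():
            sel = out.meta["modality"] == mod
            assert (y[sel] == "high").sum() == k
            assert (y[sel] == "low").sum() == k

    def test_already_balanced_unchanged(self, rng):
        sset = self.build_split_set({"pain": 3}, {"pain": 3}, rng)
        out = balance_classes_by_modality(sset)
        assert out.n_samples == 6

    def test_removal_takes_boundary_samples(self, rng):
        # high {m: 3} vs low {m: 1}: drop the 2 lowest-rated high samples
        sset = self.build_split_set({"pain": 3}, {"pain": 1}, rng)
        out = balance_classes_by_modality(sset)
        assert out.n_samples == 2
        kept_high = out.meta.loc[out.y == "high", "rating"]
        assert kept_high.tolist() == [8.0]  # ratings were 6, 7, 8


class TestPooledMedianSplitAverage:
    def test_blocked_design_counts(self, rng):
        # 51 participants x 2 modalities x 4 trials whose ratings straddle
        # the pooled median, except one participant who rates everything
        # sky-high, lands entirely in "high", and is discarded
        samples = []
        for s in range(51):
            for mod in ("pain", "touch"):
                for t, base in enumerate([2.0, 4.0, 6.0, 8.0]):
                    r = 9.0 + 0.1 * t if s == 50 else \
                        base + rng.uniform(-0.5, 0.5)
                    samples.append(trial_sample(r, mod, f"s{s:02d}", rng=rng))
        with pytest.warns(UserWarning, match="discarding"):
            sset = pooled_median_split_average(samples)
        assert (sset.y == "high").sum() == 100
        assert (sset.y == "low").sum() == 100
        assert len(set(sset.subjects.tolist())) == 50


class TestCrossDataset:
    def test_requires_normalized_inputs(self, rng):
        a = paired_noise_set(rng, normalized=False)
        b = paired_noise_set(rng, normalized=True)
        with pytest.raises(ValueError, match="normalized"):
            cross_dataset_classify(a, b)

    def test_transfers_shared_pattern(self, rng):
        def patterned(seed):
            r = np.random.default_rng(seed)
            X, y, subs = [], [], []
            for s in range(8):
                X.append(np.r_[2.0, np.zeros(9)] + r.normal(0, .5, 10))
                X.append(np.r_[-2.0, np.zeros(9)] + r.normal(0, .5, 10))
                y += ["pain", "touch"]
                subs += [f"s{s}"] * 2
            X = np.vstack(X)
            X = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            return make_set(X, y, subs, normalized=True)

        res = cross_dataset_classify(patterned(1), patterned(2), n_perm=50,
                                     seed=3)
        assert res.accuracy > 0.9
        assert res.p_value is not None
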