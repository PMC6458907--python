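"""Between-subject decoding: leave-one-subject-out (LOSO) linear SVM
classification, permutation-test null distributions, sensitivity maps,
median-split class construction, and cross-dataset generalization.

The classifier is a soft-margin linear SVM (libsvm via scikit-learn,
C = 1 by default, bias term, no internal feature scaling). All fits go
through a precomputed linear Gram matrix so that the 5000-fold permutation
retraining only touches small kernel sub-blocks; fold weight vectors are
recovered from the dual coefficients.

Sign semantics follow the "pain vs X" convention: the positive class is
listed first when a classification is defined, and a positive sensitivity
weight marks a voxel with higher signal for that class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .masks import Mask
from .preprocess import PatternSample

__all__ = [
    "SampleSet", "ClassificationResult", "SensitivityMap",
    "loso_classify", "permutation_null", "sensitivity_map",
    "consistent_sign_map", "cross_dataset_classify",
    "median_split_classes", "balance_classes_by_modality",
    "pooled_median_split_average",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SampleSet:
    """Pattern samples sharing one mask/ordering, with binary class labels.

    ``positive_class`` defines the sign convention of decision values and
    sensitivity weights.
    """

    X: np.ndarray                 # (n_samples, n_voxels)
    y: np.ndarray                 # class labels (strings)
    subjects: np.ndarray          # subject id per sample
    positive_class: str
    meta: pd.DataFrame | None = None
    normalized: bool = False
    dataset_id: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D (samples x voxels)")
        if len(self.y) != len(self.X) or len(self.subjects) != len(self.X):
            raise ValueError("labels/subjects do not match sample count")
        classes = set(map(str, np.unique(self.y)))
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {sorted(classes)}")
        if str(self.positive_class) not in classes:
            raise ValueError("positive_class not among labels")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> tuple:
        other = next(c for c in np.unique(self.y)
                     if str(c) != str(self.positive_class))
        return (self.positive_class, other)

    def signed_labels(self) -> np.ndarray:
        """+1 for the positive class, -1 otherwise."""
        return np.where(self.y.astype(str) == str(self.positive_class), 1, -1)

    @classmethod
    def from_samples(cls, samples: list, class_key: str, positive_class: str,
                     subject_key: str = "subject", dataset_id: str = "",
                     keep: tuple = ("modality", "rating", "level")) -> "SampleSet":
        if not samples:
            raise ValueError("no samples")
        X = np.vstack([s.values for s in samples])
        y = np.array([str(s.meta[class_key]) for s in samples])
        subjects = np.array([s.meta[subject_key] for s in samples])
        meta = pd.DataFrame({k: [s.meta.get(k) for s in samples]
                             for k in keep if any(k in s.meta for s in samples)})
        return cls(X=X, y=y, subjects=subjects, positive_class=str(positive_class),
                   meta=meta, normalized=all(s.normalized for s in samples),
                   dataset_id=dataset_id)

    def subset(self, idx) -> "SampleSet":
        idx = np.asarray(idx)
        return SampleSet(self.X[idx], self.y[idx], self.subjects[idx],
                         self.positive_class,
                         None if self.meta is None else
                         self.meta.iloc[idx].reset_index(drop=True),
                         self.normalized, self.dataset_id)


@dataclass
class ClassificationResult:
    accuracy: float
    fold_accuracies: np.ndarray
    fold_subjects: list
    fold_weights: np.ndarray          # (n_folds, n_voxels)
    fold_predictions: list            # signed predictions per fold
    positive_class: str
    C: float = 1.0
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None
    p_is_floor: bool = False
    n_perm: int = 0

    @property
    def weights(self) -> np.ndarray:
        """Mean of fold weight vectors (the sensitivity-map source)."""
        return self.fold_weights.mean(axis=0)

    @property
    def p_report(self) -> str:
        if self.p_value is None:
            return "n/a"
        if self.p_is_floor:
            return f"< {self.p_value:g}"
        return f"{self.p_value:g}"

    def to_dict(self) -> dict:
        d = {"accuracy": float(self.accuracy),
             "fold_accuracies": [float(a) for a in self.fold_accuracies],
             "positive_class": self.positive_class, "C": self.C,
             "n_perm": self.n_perm}
        if self.p_value is not None:
            d.update(p_value=float(self.p_value), p_is_floor=self.p_is_floor,
                     p_report=self.p_report,
                     null_mean=float(np.mean(self.null_accuracies)),
                     null_sd=float(np.std(self.null_accuracies)))
        return d


@dataclass
class SensitivityMap:
    """Per-ROI-voxel classifier weight; positive = higher signal for the
    positive (first-named) class."""

    values: np.ndarray
    mask: Mask

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.mask.voxel_count:
            raise ValueError("weight length does not match mask voxel count")

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.grid_shape)
        vol[self.mask.indices()] = self.values
        return vol

    def to_nifti(self):
        import nibabel as nib
        return nib.Nifti1Image(self.to_volume().astype(np.float32),
                               self.mask.affine)


# ---------------------------------------------------------------------------
# SVM plumbing (precomputed linear Gram)
# ---------------------------------------------------------------------------

try:  # fast path: libsvm's C solver without estimator overhead
    import sklearn.svm._libsvm as _libsvm_mod
    _libsvm_mod.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - depends on sklearn internals
    _libsvm_mod = None


class _FittedGramSVM:
    """Minimal fitted-model view exposing the attributes the decoding code
    reads (sklearn sign conventions: decision > 0 predicts classes_[1])."""

    __slots__ = ("support_", "dual_coef_", "intercept_", "classes_")

    def __init__(self, support, dual_coef, intercept, classes):
        self.support_ = support
        self.dual_coef_ = dual_coef
        self.intercept_ = intercept
        self.classes_ = classes


def _fit_gram(G_tr: np.ndarray, y_tr: np.ndarray, C: float):
    """Fit a C-SVM on a precomputed linear Gram matrix with signed labels.

    Uses libsvm's solver directly when available (the permutation loop
    refits thousands of small QPs, where estimator-level validation
    dominates); the result carries sklearn's sign conventions, which the
    test suite asserts against ``sklearn.svm.SVC`` on random instances.
    """
    if _libsvm_mod is not None:
        G = np.ascontiguousarray(G_tr, dtype=np.float64)
        y = np.ascontiguousarray(y_tr, dtype=np.float64)
        support, _, _, dual, intercept, *_ = _libsvm_mod.fit(
            G, y, svm_type=0, kernel="precomputed", C=C)
        # libsvm's raw decision is the negative of sklearn's for this call
        return _FittedGramSVM(support, -dual, -intercept,
                              np.array([-1, 1]))
    clf = SVC(kernel="precomputed", C=C)
    clf.fit(G_tr, y_tr)
    return clf

def _weights_from_dual(clf, X_tr: np.ndarray) -> np.ndarray:
    # dual_coef_ carries y_i * alpha_i for support vectors; with signed
    # labels classes_ is always [-1, +1] and decision > 0 means +1
    return clf.dual_coef_[0] @ X_tr[clf.support_]

def _predict_gram(clf, G_te_tr: np.ndarray) -> np.ndarray:
    # manual decision values: same result as clf.predict but without the
    # per-call validation overhead (matters inside the permutation loop)
    d = G_te_tr[:, clf.support_] @ clf.dual_coef_[0] + clf.intercept_[0]
    return np.where(d > 0, clf.classes_[1], clf.classes_[0])


def _loso_folds(subjects: np.ndarray) -> list:
    order = list(dict.fromkeys(subjects.tolist()))
    return [(s, np.flatnonzero(subjects != s), np.flatnonzero(subjects == s))
            for s in order]


def loso_classify(sset: SampleSet, C: float = 1.0,
                  _gram: np.ndarray | None = None) -> ClassificationResult:
    """Leave-one-subject-out classification.

    Each fold trains a linear SVM on every other subject's samples and
    tests on the held-out subject; the overall accuracy is the mean of the
    fold accuracies (each fold's accuracy being correct guesses over test
    samples). Fold weight vectors are retained for sensitivity maps.
    """
    y = sset.signed_labels()
    subjects = sset.subjects
    n_sub = len(set(subjects.tolist()))
    if n_sub < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    if n_sub == 2:
        warnings.warn("LOSO with only 2 subjects: accuracies are unstable")
    G = sset.X @ sset.X.T if _gram is None else _gram
    fold_acc, fold_w, fold_pred, fold_sub = [], [], [], []
    for s, tr, te in _loso_folds(subjects):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training data has a single class in fold {s!r}")
        clf = _fit_gram(G[np.ix_(tr, tr)], y[tr], C)
        pred = _predict_gram(clf, G[np.ix_(te, tr)])
        fold_acc.append(float(np.mean(pred == y[te])))
        fold_w.append(_weights_from_dual(clf, sset.X[tr]))
        fold_pred.append(pred)
        fold_sub.append(s)
    fold_acc = np.asarray(fold_acc)
    return ClassificationResult(
        accuracy=float(fold_acc.mean()), fold_accuracies=fold_acc,
        fold_subjects=fold_sub, fold_weights=np.vstack(fold_w),
        fold_predictions=fold_pred, positive_class=sset.positive_class, C=C)


def _p_from_null(null: np.ndarray, observed: float,
                 estimator: str = "floor") -> tuple[float, bool]:
    n = len(null)
    k = int(np.sum(null >= observed - 1e-12))
    if estimator == "plus_one":
        return (k + 1) / (n + 1), False
    if k == 0:
        return 1.0 / n, True
    return k / n, False


def permutation_null(sset: SampleSet, n_perm: int = 5000, seed: int = 0,
                     C: float = 1.0, scheme: str = "permute",
                     estimator: str = "floor") -> ClassificationResult:
    """LOSO classification plus its permutation null distribution.

    For each permutation the training labels within each fold are randomly
    exchanged (a random permutation of the training label vector, which
    preserves class counts; ``scheme="resample"`` draws labels iid instead),
    the classifier is retrained and tested against the held-out subject's
    true labels; the mean fold accuracy is one null draw. The p-value is the
    proportion of null accuracies at or above the observed one, reported as
    "< 1/n_perm" when no permutation reaches it (``estimator="plus_one"``
    switches to the (k+1)/(n+1) convention).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    G = sset.X @ sset.X.T
    result = loso_classify(sset, C=C, _gram=G)
    y = sset.signed_labels()
    folds = _loso_folds(sset.subjects)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        accs = []
        for s, tr, te in folds:
            if scheme == "permute":
                y_tr = y[tr][rng.permutation(len(tr))]
            elif scheme == "resample":
                y_tr = rng.choice([-1, 1], size=len(tr))
            else:
                raise ValueError(f"unknown scheme {scheme!r}")
            if len(np.unique(y_tr)) < 2:  # degenerate resample draw
                accs.append(float(np.mean(y[te] == y_tr[0])))
                continue
            clf = _fit_gram(G[np.ix_(tr, tr)], y_tr, C)
            accs.append(float(np.mean(_predict_gram(clf, G[np.ix_(te, tr)]) == y[te])))
        null[i] = np.mean(accs)
    p, floored = _p_from_null(null, result.accuracy, estimator)
    result.null_accuracies = null
    result.p_value = p
    result.p_is_floor = floored
    result.n_perm = n_perm
    return result


# ---------------------------------------------------------------------------
# sensitivity maps
# ---------------------------------------------------------------------------

def sensitivity_map(result: ClassificationResult, mask: Mask,
                    source: str = "fold_mean") -> SensitivityMap:
    """Map classifier weights back onto ROI voxels.

    ``source="fold_mean"`` (default) averages the fold weight vectors;
    no refit, no leakage. A full-data refit is available by passing a
    result whose single fold covers all data (e.g. cross-dataset training).
    """
    if source != "fold_mean":
        raise ValueError("only source='fold_mean' is implemented")
    return SensitivityMap(result.weights, mask)


def consistent_sign_map(maps: list) -> SensitivityMap:
    """Keep voxels whose weight sign agrees across all maps, valued at the
    across-map average weight; all other voxels are zeroed."""
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    m0 = maps[0].mask
    for m in maps[1:]:
        if m.mask.grid_shape != m0.grid_shape or \
                not np.allclose(m.mask.affine, m0.affine) or \
                not np.array_equal(m.mask.data, m0.data):
            raise ValueError("maps are defined on different masks")
    V = np.vstack([m.values for m in maps])
    signs = np.sign(V)
    consistent = np.all(signs == signs[0], axis=0) & (signs[0] != 0)
    avg = V.mean(axis=0)
    return SensitivityMap(np.where(consistent, avg, 0.0), m0)


# ---------------------------------------------------------------------------
# cross-dataset generalization
# ---------------------------------------------------------------------------

def cross_dataset_classify(train: SampleSet, test: SampleSet, C: float = 1.0,
                           n_perm: int = 0, seed: int = 0,
                           estimator: str = "floor") -> ClassificationResult:
    """Train one model on an entire dataset, test on another.

    Both sets must be ROI-normalized (amplitude differences between scanners
    carry no transferable information) and share voxel ordering. The
    permutation null retrains on label-permuted training data.
    """
    if not train.normalized or not test.normalized:
        raise ValueError("cross-dataset classification requires ROI-normalized samples")
    if train.X.shape[1] != test.X.shape[1]:
        raise ValueError("train/test voxel counts differ (mask mismatch)")
    if str(train.positive_class) != str(test.positive_class):
        raise ValueError("positive classes differ between sets")
    y_tr, y_te = train.signed_labels(), test.signed_labels()
    G_tr = train.X @ train.X.T
    G_te = test.X @ train.X.T
    clf = _fit_gram(G_tr, y_tr, C)
    pred = _predict_gram(clf, G_te)
    acc = float(np.mean(pred == y_te))
    w = _weights_from_dual(clf, train.X)
    result = ClassificationResult(
        accuracy=acc, fold_accuracies=np.array([acc]),
        fold_subjects=["all"], fold_weights=w[None, :],
        fold_predictions=[pred], positive_class=train.positive_class, C=C)
    if n_perm:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            y_p = y_tr[rng.permutation(len(y_tr))]
            clf_p = _fit_gram(G_tr, y_p, C)
            null[i] = np.mean(_predict_gram(clf_p, G_te) == y_te)
        p, floored = _p_from_null(null, acc, estimator)
        result.null_accuracies = null
        result.p_value = p
        result.p_is_floor = floored
        result.n_perm = n_perm
    return result


# ---------------------------------------------------------------------------
# median-split class construction
# ---------------------------------------------------------------------------

def median_split_classes(samples: list, rating_key: str = "rating",
                         subject_key: str = "subject",
                         dataset_id: str = "") -> SampleSet:
    """Pool samples across modalities, sort by rating, and split at the
    pooled median: strictly above goes to "high", at-or-below goes to "low"
    (ties to "low" by convention)."""
    ratings = np.array([float(s.meta[rating_key]) for s in samples])
    if np.allclose(ratings, ratings[0]):
        raise ValueError("all ratings identical: median split is degenerate")
    med = float(np.median(ratings))
    labeled = []
    for s, r in zip(samples, ratings):
        s2 = PatternSample(s.values, meta=dict(s.meta), normalized=s.normalized)
        s2.meta["class"] = "high" if r > med else "low"
        labeled.append(s2)
    return SampleSet.from_samples(labeled, class_key="class",
                                  positive_class="high",
                                  subject_key=subject_key,
                                  dataset_id=dataset_id,
                                  keep=("modality", "rating", "level", "class"))


def balance_classes_by_modality(sset: SampleSet,
                                rating_key: str = "rating") -> SampleSet:
    """Equalize per-modality sample counts between the high and low classes.

    For each modality, min(high, low) samples are kept per class; the excess
    is removed from the boundary of the larger class — the lowest-rated
    samples from "high" and the highest-rated samples from "low". A modality
    present in only one class is dropped entirely with a warning. Rating
    ties at the removal boundary break by position (first kept).
    """
    if sset.meta is None or rating_key not in sset.meta:
        raise ValueError("sample set carries no ratings")
    mods = sset.meta["modality"].to_numpy()
    ratings = sset.meta[rating_key].to_numpy(dtype=float)
    y = sset.y.astype(str)
    keep = np.zeros(sset.n_samples, dtype=bool)
    for m in dict.fromkeys(mods.tolist()):
        hi = np.flatnonzero((mods == m) & (y == "high"))
        lo = np.flatnonzero((mods == m) & (y == "low"))
        if len(hi) == 0 or len(lo) == 0:
            warnings.warn(f"modality {m!r} absent from one class; dropped")
            continue
        k = min(len(hi), len(lo))
        # keep the k highest-rated in "high", the k lowest-rated in "low"
        hi_keep = hi[np.argsort(-ratings[hi], kind="stable")[:k]]
        lo_keep = lo[np.argsort(ratings[lo], kind="stable")[:k]]
        keep[hi_keep] = True
        keep[lo_keep] = True
    if not keep.any():
        raise ValueError("balancing removed every sample")
    return sset.subset(np.flatnonzero(keep))


def pooled_median_split_average(samples: list, rating_key: str = "rating",
                                subject_key: str = "subject",
                                modality_key: str = "modality",
                                dataset_id: str = "") -> SampleSet:
    """Blocked-design high/low construction: median-split all trials pooled
    across modalities and participants, discard participants whose trials
    all fall in one class, then average per modality x participant x class.

    With every participant retained in both classes, each class holds
    (participants x modalities) samples.
    """
    split = median_split_classes(samples, rating_key=rating_key,
                                 subject_key=subject_key)
    y = split.y.astype(str)
    subjects = split.subjects
    # participants contributing to only one class are discarded
    keep_subjects = {s for s in set(subjects.tolist())
                     if len(set(y[subjects == s])) == 2}
    dropped = sorted(set(subjects.tolist()) - keep_subjects)
    if dropped:
        warnings.warn(f"discarding participants in a single class: {dropped}")
    rebuilt = []
    for i in range(split.n_samples):
        if subjects[i] not in keep_subjects:
            continue
        meta = {subject_key: subjects[i], "class": y[i],
                "modality": split.meta["modality"].iloc[i],
                rating_key: split.meta[rating_key].iloc[i]}
        rebuilt.append(PatternSample(split.X[i], meta=meta,
                                     normalized=split.normalized))
    from .preprocess import average_samples
    averaged = average_samples(rebuilt, by=(subject_key, modality_key, "class"))
    return SampleSet.from_samples(averaged, class_key="class",
                                  positive_class="high",
                                  subject_key=subject_key,
                                  dataset_id=dataset_id,
                                  keep=("modality", rating_key, "class"))
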