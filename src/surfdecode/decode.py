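"""Leave-one-run-out linear-SVM decoding of condition contrasts.

A contrast names two disjoint condition sets (class A / class B); the
pooled "Matte" class is the union of the two control conditions. For
each cross-validation fold one run is held out, the classifier is
trained on all remaining runs — optionally subsampling the majority
class to balance training (pooled contrasts) — and the fold accuracy is
the fraction of held-out patterns classified correctly. Test sets are
never subsampled. The decision rule is the standard soft-margin linear
SVM (hinge loss, regularisation parameter C).

Two numerically identical engines are provided: ``svc`` fits
``sklearn.svm.SVC(kernel="linear")`` on the raw patterns, while
``gram`` runs the same libsvm solver on a precomputed linear Gram
matrix, which amortises the kernel computation across the thousands of
refits a permutation test needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from . import _fastsvm
from .patterns import PatternSet

MATTE = ("GC", "RC")

STANDARD_CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "G_vs_R": (("G",), ("R",)),
    "GC_vs_RC": (("GC",), ("RC",)),
    "G_vs_M": (("G",), MATTE),
    "R_vs_M": (("R",), MATTE),
}


@dataclass(frozen=True)
class ContrastSpec:
    """Binary contrast between two disjoint condition sets."""

    name: str
    class_a: tuple[str, ...]
    class_b: tuple[str, ...]
    balance_training: bool = True

    def __post_init__(self) -> None:
        if not self.class_a or not self.class_b:
            raise ValueError("both classes must be non-empty")
        if set(self.class_a) & set(self.class_b):
            raise ValueError("classes must be disjoint")

    @classmethod
    def named(cls, name: str, balance_training: bool = True) -> "ContrastSpec":
        if name not in STANDARD_CONTRASTS:
            raise KeyError(
                f"unknown contrast {name!r}; have {sorted(STANDARD_CONTRASTS)}"
            )
        a, b = STANDARD_CONTRASTS[name]
        return cls(name, a, b, balance_training)


@dataclass
class Dataset:
    """Labelled patterns grouped by run for cross-validation."""

    X: np.ndarray          # patterns x voxels
    y: np.ndarray          # 0 = class A, 1 = class B
    runs: np.ndarray
    contrast: ContrastSpec

    @property
    def n_runs(self) -> int:
        return len(np.unique(self.runs))


@dataclass
class DecodingResult:
    contrast: str
    roi: str
    participant_id: int
    fold_accuracies: np.ndarray
    n_train_per_class: int
    n_test_per_fold: np.ndarray
    mean_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        self.mean_accuracy = float(self.fold_accuracies.mean())

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracies)


def assemble_dataset(ps: PatternSet, contrast: ContrastSpec) -> Dataset:
    """Binary-label the patterns belonging to the contrast's classes.

    Requires centered patterns and at least one pattern of each class in
    every run (so every fold has both training classes and a non-empty
    test set). Pooled classes keep all their patterns — test folds may
    be unbalanced.
    """
    if not ps.centered:
        raise ValueError("patterns must be centered before decoding")
    in_a = np.isin(ps.conditions, contrast.class_a)
    in_b = np.isin(ps.conditions, contrast.class_b)
    keep = in_a | in_b
    y = np.where(in_a[keep], 0, 1)
    runs = ps.runs[keep]
    for r in np.unique(ps.runs):
        m = runs == r
        if m.sum() == 0 or len(np.unique(y[m])) < 2:
            raise ValueError(
                f"run {r} lacks patterns for both classes of {contrast.name}"
            )
    return Dataset(X=ps.X[keep], y=y, runs=runs, contrast=contrast)


def train_linear_classifier(
    X: np.ndarray, y: np.ndarray, c_param: float = 1.0
) -> SVC:
    """Fit the linear maximum-margin classifier on a training set."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = SVC(kernel="linear", C=c_param)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def _balanced_train_indices(
    y: np.ndarray,
    runs: np.ndarray,
    tr_idx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Seeded subsample of the majority class to match the minority,
    applied within each training run.

    Per-run (rather than global) subsampling keeps both classes evenly
    represented across runs; because picking the kept patterns of each
    class within a run is then symmetric between classes, the shuffled-
    label null stays exactly unbiased even with within-run signal
    correlations (a globally subsampled majority class overweights some
    runs, which measurably tilts null predictions toward it).
    """
    keep = []
    for r in np.unique(runs[tr_idx]):
        m = tr_idx[runs[tr_idx] == r]
        a = m[y[m] == 0]
        b = m[y[m] == 1]
        n = min(len(a), len(b))
        if len(a) > n:
            a = rng.choice(a, size=n, replace=False)
        if len(b) > n:
            b = rng.choice(b, size=n, replace=False)
        keep.append(a)
        keep.append(b)
    return np.sort(np.concatenate(keep))


def _fold_indices(runs: np.ndarray) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(held-out run, train indices, test indices) per fold, in run order."""
    folds = []
    for r in np.unique(runs):
        te = np.flatnonzero(runs == r)
        tr = np.flatnonzero(runs != r)
        folds.append((int(r), tr, te))
    return folds


def _fold_accuracy_gram(
    G: np.ndarray,
    y: np.ndarray,
    tr_idx: np.ndarray,
    te_idx: np.ndarray,
    c_param: float,
) -> float:
    """Accuracy of one fold using the precomputed linear Gram matrix."""
    pred = _fastsvm.svm_predict_gram(
        np.ascontiguousarray(G[np.ix_(tr_idx, tr_idx)]),
        y[tr_idx],
        np.ascontiguousarray(G[np.ix_(te_idx, tr_idx)]),
        c_param,
    )
    return float(np.mean(pred == y[te_idx]))


def loro_cv(
    ds: Dataset,
    c_param: float = 1.0,
    seed=None,
    roi: str = "roi",
    participant_id: int = 0,
    engine: str = "svc",
    gram: np.ndarray | None = None,
) -> DecodingResult:
    """Leave-one-run-out cross-validation of the contrast's decoder.

    One fold per run; if the contrast balances training, the majority
    training class is subsampled with the seeded generator. ``engine``
    selects the raw-feature SVC path or the precomputed-Gram libsvm path
    (identical predictions); a Gram matrix can be passed in to avoid
    recomputation.
    """
    if ds.n_runs < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    rng = np.random.default_rng(seed)
    if engine == "gram" and gram is None:
        gram = ds.X @ ds.X.T

    accs, ntests = [], []
    n_train = None
    for _, tr_idx, te_idx in _fold_indices(ds.runs):
        if ds.contrast.balance_training:
            tr_idx = _balanced_train_indices(ds.y, ds.runs, tr_idx, rng)
        n_train = int(np.minimum(
            (ds.y[tr_idx] == 0).sum(), (ds.y[tr_idx] == 1).sum()
        ))
        if engine == "svc":
            clf = train_linear_classifier(ds.X[tr_idx], ds.y[tr_idx], c_param)
            pred = clf.predict(ds.X[te_idx])
            accs.append(float(np.mean(pred == ds.y[te_idx])))
        elif engine == "gram":
            accs.append(
                _fold_accuracy_gram(gram, ds.y, tr_idx, te_idx, c_param)
            )
        else:
            raise ValueError(f"unknown engine {engine!r}")
        ntests.append(len(te_idx))

    return DecodingResult(
        contrast=ds.contrast.name,
        roi=roi,
        participant_id=participant_id,
        fold_accuracies=np.array(accs),
        n_train_per_class=n_train,
        n_test_per_fold=np.array(ntests),
    )
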