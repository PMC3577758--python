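"""Target/non-target classification with a linear soft-margin SVM.

The classifier minimizes  (1/2)|a|^2 + C * sum_i xi_i  subject to
y_i (a . x_i + b) >= 1 - xi_i, xi_i >= 0 — the standard soft-margin primal.
Model selection follows a three-way split: half the target trials plus an
equal number of non-target trials train the classifier, and the remaining
samples are divided equally into a C-searching set (grid 2^-16 .. 2^2) and a
test set. The whole analysis is repeated with re-randomized splits, and
bootstrap trial-averaging (averaging k same-class epochs before feature
extraction) trades selection time for signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .features import FULL_WINDOW, ErpFeatureExtractor
from .preprocess import EpochSet

DEFAULT_C_GRID = tuple(2.0**m for m in range(-16, 3))


@dataclass(frozen=True)
class SplitConfig:
    """Three-way split and repetition scheme."""

    train_target_fraction: float = 0.5
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_grid:
            raise ValueError("C grid must be nonempty")
        if self.n_repetitions < 1:
            raise ValueError("need at least one repetition")


@dataclass
class AccuracyRecord:
    """Per-class and overall accuracies (percent) for one evaluation."""

    target_accuracy: float
    nontarget_accuracy: float
    overall_accuracy: float
    n_test: int
    k_averaged: int = 1
    repetition: int = 0
    variant: str = ""
    best_C: float | None = None


class SoftMarginLinearSVM(BaseEstimator, ClassifierMixin):
    """Linear soft-margin SVM with the exact hinge-loss primal objective.

    Thin estimator over :class:`sklearn.svm.SVC` with a linear kernel (an
    SMO solver for this exact objective), exposing the weight vector ``a``
    as ``coef_`` and the offset ``b`` as ``intercept_``. Decisions are
    sign(a . x + b), with the boundary value 0 classified as +1.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-6):
        self.C = C
        self.tol = tol

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftMarginLinearSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) != {-1, 1}:
            raise ValueError("training set must contain both labels (+1 and -1)")
        svc = SVC(kernel="linear", C=self.C, tol=self.tol, shrinking=True)
        svc.fit(X, y)
        self.coef_ = svc.coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0.0, 1, -1)

    def objective(self, X: np.ndarray, y: np.ndarray) -> float:
        """Primal objective value (1/2)|a|^2 + C * sum hinge(x_i, y_i)."""
        margins = y * self.decision_function(X)
        hinge = np.clip(1.0 - margins, 0.0, None)
        return 0.5 * float(self.coef_ @ self.coef_) + self.C * float(hinge.sum())


def train_soft_margin(X: np.ndarray, y: np.ndarray, C: float) -> SoftMarginLinearSVM:
    """Functional wrapper: fit the soft-margin SVM at a given C."""
    return SoftMarginLinearSVM(C=C).fit(X, y)


def split_three_way(
    labels: np.ndarray, seed: int, train_target_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index partition into (train, C-search, test).

    Train takes floor(fraction * n_targets) targets plus an equal number of
    randomly chosen non-targets; the remaining samples are split equally at
    random into C-search and test, with an odd remainder's extra sample
    going to the test set. The three sets are disjoint and exhaustive.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    targets = np.flatnonzero(labels == 1)
    nontargets = np.flatnonzero(labels == -1)
    n_train_t = int(len(targets) * train_target_fraction)
    if len(targets) < 2 or n_train_t < 1:
        raise ValueError(f"too few target samples ({len(targets)}) to split")
    if len(nontargets) < n_train_t:
        raise ValueError("not enough non-targets to balance the training set")

    train_t = rng.choice(targets, size=n_train_t, replace=False)
    train_n = rng.choice(nontargets, size=n_train_t, replace=False)
    train = np.concatenate([train_t, train_n])
    remaining = np.setdiff1d(np.arange(len(labels)), train)
    remaining = rng.permutation(remaining)
    n_c = len(remaining) // 2
    return np.sort(train), np.sort(remaining[:n_c]), np.sort(remaining[n_c:])


def select_C(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_search: np.ndarray,
    y_search: np.ndarray,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
) -> tuple[float, dict[float, float]]:
    """Grid-search C on the C-searching set; ties go to the smallest C.

    Selection uses overall accuracy on the search set. A grid value whose
    fit fails is skipped (recorded as NaN) rather than aborting the search.
    """
    accs: dict[float, float] = {}
    best_c, best_acc = None, -np.inf
    for C in sorted(c_grid):
        try:
            model = SoftMarginLinearSVM(C=C).fit(X_train, y_train)
        except Exception:
            accs[C] = float("nan")
            continue
        acc = float(np.mean(model.predict(X_search) == y_search))
        accs[C] = 100.0 * acc
        if acc > best_acc:  # strict: earlier (smaller) C wins ties
            best_c, best_acc = C, acc
    if best_c is None:
        raise ValueError("no C in the grid produced a trainable model")
    return best_c, accs


def evaluate(
    model: SoftMarginLinearSVM, X: np.ndarray, y: np.ndarray
) -> AccuracyRecord:
    """Target, non-target and overall accuracy (percent) on a test set."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X)
    correct = pred == y

    def class_acc(label: int) -> float:
        m = y == label
        if not m.any():  # class absent: accuracy undefined, flagged as NaN
            return float("nan")
        return 100.0 * float(correct[m].mean())

    return AccuracyRecord(
        target_accuracy=class_acc(1),
        nontarget_accuracy=class_acc(-1),
        overall_accuracy=100.0 * float(correct.mean()),
        n_test=len(y),
    )


def bootstrap_average(
    epochs: EpochSet, k: int, seed: int, resample_single: bool = False
) -> EpochSet:
    """Average k same-class epochs per output sample, keeping sample counts.

    For every kept trial, k trials are drawn at random (without replacement
    within one replicate; pools are reused with fresh draws across
    replicates) from the trial's class pool and their epochs averaged.
    Target pools are per stimulus direction; non-target trials are pooled
    across directions, whose per-direction counts are small. The output has
    exactly as many samples per class as the single-trial data. k=1 returns
    the original trials unless ``resample_single`` asks for a resample.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    base = epochs.kept()
    if k == 1 and not resample_single:
        return base
    rng = np.random.default_rng(seed)
    n = base.n_trials
    new_epochs = np.empty_like(base.epochs)
    for i in range(n):
        if base.labels[i] == 1:
            pool = np.flatnonzero(
                (base.labels == 1) & (base.directions == base.directions[i])
            )
        else:
            pool = np.flatnonzero(base.labels == -1)
        if len(pool) < k:
            raise ValueError(
                f"class pool of size {len(pool)} too small to average k={k} trials"
            )
        draw = rng.choice(pool, size=k, replace=False)
        new_epochs[i] = base.epochs[draw].mean(axis=0)
    return replace(base, epochs=new_epochs)


@dataclass(frozen=True)
class Variant:
    """A feature-extraction configuration (channel set x analysis window)."""

    channel_set: str = "64"
    window_ms: tuple[float, float] = FULL_WINDOW

    @property
    def tag(self) -> str:
        lo, hi = self.window_ms
        return f"ch{self.channel_set}_{int(lo)}-{int(hi)}ms"


def run_experiment(
    epochs: EpochSet,
    config: SplitConfig = SplitConfig(),
    variants: tuple[Variant, ...] = (Variant(),),
    k_range: tuple[int, ...] = tuple(range(1, 11)),
) -> pd.DataFrame:
    """Full factorial: repetitions x averaging counts x feature variants.

    Per cell, epochs are bootstrap-averaged, features extracted, the
    three-way split drawn, C grid-searched, and test-set accuracy recorded.
    Returns a tidy frame with one row per (repetition, k, variant). A cell
    whose pipeline fails is recorded with NaN accuracies rather than
    aborting the factorial.
    """
    root = np.random.SeedSequence(config.seed)
    rep_seeds = root.generate_state(config.n_repetitions * 2).reshape(-1, 2) % (2**31)
    extractors = {v.tag: ErpFeatureExtractor(v.channel_set, v.window_ms).fit() for v in variants}
    rows = []
    for rep in range(config.n_repetitions):
        boot_seed, split_seed = (int(s) for s in rep_seeds[rep])
        for k in k_range:
            try:
                averaged = bootstrap_average(epochs, k, seed=boot_seed + k)
            except ValueError:
                averaged = None
            for v in variants:
                if averaged is None:
                    rows.append(_nan_row(k, rep, v.tag))
                    continue
                try:
                    X = extractors[v.tag].transform(averaged)
                    y = averaged.labels
                    tr, cs, te = split_three_way(
                        y, seed=split_seed, train_target_fraction=config.train_target_fraction
                    )
                    best_c, _ = select_C(X[tr], y[tr], X[cs], y[cs], config.c_grid)
                    model = SoftMarginLinearSVM(C=best_c).fit(X[tr], y[tr])
                    rec = evaluate(model, X[te], y[te])
                    rec.k_averaged, rec.repetition, rec.variant, rec.best_C = (
                        k,
                        rep,
                        v.tag,
                        best_c,
                    )
                    rows.append(rec)
                except ValueError:
                    rows.append(_nan_row(k, rep, v.tag))
    return pd.DataFrame([r.__dict__ for r in rows])


def _nan_row(k: int, rep: int, tag: str) -> AccuracyRecord:
    return AccuracyRecord(
        target_accuracy=float("nan"),
        nontarget_accuracy=float("nan"),
        overall_accuracy=float("nan"),
        n_test=0,
        k_averaged=k,
        repetition=rep,
        variant=tag,
    )


def mean_accuracy_by_k(results: pd.DataFrame, variant: str | None = None) -> pd.Series:
    """Mean overall accuracy across repetitions, indexed by averaging count."""
    df = results if variant is None else results[results["variant"] == variant]
    return df.groupby("k_averaged")["overall_accuracy"].mean()


def averaging_trend(results: pd.DataFrame, variant: str | None = None) -> float:
    """Spearman rank correlation between k and mean accuracy (Fig-6A-style)."""
    by_k = mean_accuracy_by_k(results, variant)
    rho, _ = stats.spearmanr(by_k.index.to_numpy(), by_k.to_numpy())
    return float(rho)
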