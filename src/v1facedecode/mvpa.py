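"""Multivariate decoding of single-trial response patterns.

The decoding contract mirrors standard neuroimaging MVPA practice:

* per-feature min-max normalization of the TRAINING data into [-1, 1], with
  the identical affine map (same min, max, range) applied to test data,
  which may therefore fall outside the range;
* a linear support-vector machine (libsvm via scikit-learn) with cost C = 1,
  one-vs-one voting for the three-way problem;
* leave-one-run-out cross-validation: the classifier is trained on n-1 runs
  and tested on the held-out run, for each of the n partitions, so training
  and test trials never share a run;
* test either on independent single trials or on the per-class average test
  pattern (raw betas are averaged before normalization is applied);
* random feature sub-sampling (30 draws per set size, 15 sizes up to 160)
  to equate feature counts across regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC

__all__ = [
    "TrialPatternSet",
    "NormalizationParams",
    "DecodingResult",
    "FoldDetail",
    "GroupTest",
    "fit_normalizer",
    "apply_normalizer",
    "subsample_schedule",
    "draw_subsets",
    "train_linear_classifier",
    "loro_cv",
    "subsample_curve",
    "group_performance_test",
]


@dataclass
class TrialPatternSet:
    """Single-trial betas (trials x features) with class and run labels."""

    betas: np.ndarray
    labels: np.ndarray
    run_ids: np.ndarray
    task: str = ""
    region: str = ""
    classification: str = ""

    def __post_init__(self) -> None:
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        self.labels = np.asarray(self.labels)
        self.run_ids = np.asarray(self.run_ids)
        n = self.betas.shape[0]
        if self.labels.shape[0] != n or self.run_ids.shape[0] != n:
            raise ValueError("betas, labels and run_ids must align row-wise")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_features(self) -> int:
        return self.betas.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run_ids)


@dataclass
class NormalizationParams:
    """Per-feature min/max learned from training data.

    The transform is ``x -> 2 (x - min) / range - 1``; constant features
    (range 0) map to 0 so the transform stays total and bounded.
    """

    feature_min: np.ndarray
    feature_max: np.ndarray

    @property
    def feature_range(self) -> np.ndarray:
        return self.feature_max - self.feature_min

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.feature_min.size:
            raise ValueError("feature count does not match normalization parameters")
        rng = self.feature_range
        safe = np.where(rng > 0, rng, 1.0)
        out = 2.0 * (X - self.feature_min) / safe - 1.0
        return np.where(rng > 0, out, 0.0)


def fit_normalizer(train) -> NormalizationParams:
    """Learn per-feature min/max from training patterns (rows x features)."""
    X = np.atleast_2d(np.asarray(getattr(train, "betas", train), dtype=float))
    if X.shape[0] < 1:
        raise ValueError("at least one training row is required")
    return NormalizationParams(feature_min=X.min(axis=0), feature_max=X.max(axis=0))


def apply_normalizer(params: NormalizationParams, test):
    """Apply training normalization to test patterns (values may exceed [-1, 1])."""
    if isinstance(test, TrialPatternSet):
        return TrialPatternSet(
            betas=params.transform(test.betas),
            labels=test.labels,
            run_ids=test.run_ids,
            task=test.task,
            region=test.region,
            classification=test.classification,
        )
    return params.transform(test)


def subsample_schedule(max_features: int, n_sizes: int = 15, cap: int = 160) -> np.ndarray:
    """Strictly increasing feature set sizes from 1 to min(max_features, cap).

    Evenly spaced (after rounding) with ``n_sizes`` entries; when fewer than
    ``n_sizes`` distinct sizes exist the schedule shrinks with a warning.
    """
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    upper = min(max_features, cap)
    sizes = np.unique(np.round(np.linspace(1, upper, n_sizes)).astype(int))
    if sizes.size < n_sizes:
        warnings.warn(
            f"only {sizes.size} distinct set sizes available up to {upper}", stacklevel=2
        )
    return sizes


def draw_subsets(n_features: int, size: int, n_draws: int = 30, seed: int = 0) -> list[np.ndarray]:
    """``n_draws`` independent without-replacement feature index draws."""
    if size > n_features:
        raise ValueError("subset size exceeds available features")
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(n_features, size=size, replace=False)) for _ in range(n_draws)]


def train_linear_classifier(X: np.ndarray, y: np.ndarray, cost: float = 1.0) -> SVC:
    """Linear max-margin classifier (libsvm), one-vs-one for >2 classes."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    clf = SVC(kernel="linear", C=cost)
    clf.fit(np.atleast_2d(X), y)
    return clf


@dataclass
class FoldDetail:
    test_run: object
    train_runs: tuple
    train_rows: np.ndarray
    test_rows: np.ndarray
    normalization: NormalizationParams
    accuracy: dict  # test_mode -> %


@dataclass
class DecodingResult:
    """Accuracy of one decoding problem (region x task x classification)."""

    region: str
    task: str
    classification: str
    accuracies: np.ndarray  # per fold, %
    test_mode: str
    set_size: int
    folds: list = field(default_factory=list, repr=False)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def _fold_accuracies(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    cost: float,
) -> tuple[dict, NormalizationParams]:
    """Train once, score single-trial and class-averaged test modes."""
    params = fit_normalizer(train_X)
    clf = train_linear_classifier(params.transform(train_X), train_y, cost=cost)
    single = 100.0 * np.mean(clf.predict(params.transform(test_X)) == test_y)
    classes = np.unique(test_y)
    avg_X = np.stack([test_X[test_y == c].mean(axis=0) for c in classes])
    averaged = 100.0 * np.mean(clf.predict(params.transform(avg_X)) == classes)
    return {"single_trial": float(single), "averaged": float(averaged)}, params


def loro_cv(
    patterns: TrialPatternSet,
    cost: float = 1.0,
    test_mode: str = "single_trial",
    feature_indices: np.ndarray | None = None,
) -> DecodingResult:
    """Leave-one-run-out cross-validation.

    One fold per run; normalization parameters are fitted on the training
    folds only and applied unchanged to the held-out run.  ``test_mode``
    ``"single_trial"`` scores every held-out trial; ``"averaged"`` scores the
    per-class mean of the held-out raw betas.  Folds whose training runs lack
    a class are skipped with a warning.
    """
    if test_mode not in ("single_trial", "averaged"):
        raise ValueError("test_mode must be 'single_trial' or 'averaged'")
    runs = patterns.runs
    if runs.size < 2:
        raise ValueError("leave-one-run-out needs at least two runs")
    classes = patterns.classes
    X = patterns.betas if feature_indices is None else patterns.betas[:, feature_indices]
    folds: list[FoldDetail] = []
    for run in runs:
        test_rows = np.flatnonzero(patterns.run_ids == run)
        train_rows = np.flatnonzero(patterns.run_ids != run)
        train_y = patterns.labels[train_rows]
        if np.unique(train_y).size < classes.size:
            warnings.warn(f"fold {run!r} skipped: a class is absent from training runs", stacklevel=2)
            continue
        acc, params = _fold_accuracies(
            X[train_rows], train_y, X[test_rows], patterns.labels[test_rows], cost
        )
        folds.append(
            FoldDetail(
                test_run=run,
                train_runs=tuple(r for r in runs if r != run),
                train_rows=train_rows,
                test_rows=test_rows,
                normalization=params,
                accuracy=acc,
            )
        )
    return DecodingResult(
        region=patterns.region,
        task=patterns.task,
        classification=patterns.classification,
        accuracies=np.array([f.accuracy[test_mode] for f in folds]),
        test_mode=test_mode,
        set_size=X.shape[1],
        folds=folds,
    )


def subsample_curve(
    patterns: TrialPatternSet,
    sizes: np.ndarray | None = None,
    n_draws: int = 30,
    cost: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy as a function of feature set size.

    For every fold, size and draw a random feature subset is selected (seeded
    deterministically from (seed, fold, size, draw)), one classifier is
    trained and both test modes are scored; accuracies are averaged over
    draws within a fold, then over folds.  Returns a tidy frame with columns
    ``set_size``, ``test_mode``, ``accuracy``.
    """
    if sizes is None:
        sizes = subsample_schedule(patterns.n_features)
    runs = patterns.runs
    if runs.size < 2:
        raise ValueError("leave-one-run-out needs at least two runs")
    classes = patterns.classes
    records = []
    for size in sizes:
        fold_acc = {"single_trial": [], "averaged": []}
        for fi, run in enumerate(runs):
            test_rows = patterns.run_ids == run
            train_rows = ~test_rows
            train_y = patterns.labels[train_rows]
            if np.unique(train_y).size < classes.size:
                continue
            draw_acc = {"single_trial": [], "averaged": []}
            for d in range(n_draws):
                subset_seed = int(
                    np.random.SeedSequence([seed, fi, int(size), d]).generate_state(1)[0] % (2**31)
                )
                (subset,) = draw_subsets(patterns.n_features, int(size), n_draws=1, seed=subset_seed)
                acc, _ = _fold_accuracies(
                    patterns.betas[np.ix_(train_rows, subset)],
                    train_y,
                    patterns.betas[np.ix_(test_rows, subset)],
                    patterns.labels[test_rows],
                    cost,
                )
                for mode in draw_acc:
                    draw_acc[mode].append(acc[mode])
            for mode in fold_acc:
                fold_acc[mode].append(np.mean(draw_acc[mode]))
        for mode, vals in fold_acc.items():
            records.append(
                {"set_size": int(size), "test_mode": mode, "accuracy": float(np.mean(vals))}
            )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class GroupTest:
    t: float
    p: float
    dof: int


def group_performance_test(per_subject_accuracy, chance: float) -> GroupTest:
    """One-sample, one-tailed (upper) t-test of group accuracy against chance."""
    acc = np.asarray(per_subject_accuracy, dtype=float)
    if acc.size < 2:
        raise ValueError("group test needs at least two datasets")
    dof = acc.size - 1
    sd = acc.std(ddof=1)
    if sd == 0:
        if np.isclose(acc.mean(), chance):
            return GroupTest(t=0.0, p=0.5, dof=dof)
        t = np.inf if acc.mean() > chance else -np.inf
        return GroupTest(t=float(t), p=float(sps.t.sf(t, dof)), dof=dof)
    t = (acc.mean() - chance) / (sd / np.sqrt(acc.size))
    return GroupTest(t=float(t), p=float(sps.t.sf(t, dof)), dof=dof)
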