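"""Group statistics and the classifier-evaluation harness.

Group descriptors are summarized as median and interquartile range and
compared with the Mann-Whitney U test (significance at P <= 0.01). The
classification harness labels animals against a gold standard derived from
D2 (3rd quartile of the control animals as threshold, strict >), then
trains an RBF-kernel SVM per descriptor set: grid search over exponentially
growing kernel-width/soft-margin sequences, cross-validated on a stratified
60% training split, ROC/AUC/f1 measured on the held-out 40%.

Quantiles everywhere use linear interpolation (NumPy's default, type 7).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import f1_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "GridSearchConfig",
    "ROCResult",
    "summarize_group",
    "mann_whitney_u",
    "gold_standard_labels",
    "train_and_evaluate",
    "best_feature_combination",
    "SIGNIFICANCE_LEVEL",
]

#: Two-sided significance level used to flag group differences.
SIGNIFICANCE_LEVEL = 0.01

#: Largest combined sample size handled by the exact U-test branch.
_EXACT_N_MAX = 12


def summarize_group(values: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    ``U`` is the statistic of the first sample. The exact null distribution
    is enumerated when the combined size is <= 12 and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size + b.size <= _EXACT_N_MAX and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def gold_standard_labels(
    table: pd.DataFrame,
    d2_column: str = "D2",
    group_column: str = "group",
    control_group: str = "control",
) -> pd.Series:
    """Binary disease labels from the D2 gold standard.

    The threshold is the 3rd quartile of the control animals' D2 (linear
    interpolation); an animal is labeled diseased iff its D2 is strictly
    above the threshold. Returns a boolean Series aligned with the table.
    """
    controls = table.loc[table[group_column] == control_group, d2_column].dropna()
    if controls.empty:
        raise ValueError("no control animals with a D2 value")
    threshold = float(np.percentile(controls.to_numpy(dtype=float), 75))
    return (table[d2_column] > threshold).rename("diseased")


def _decades(lo_exp: int, hi_exp: int) -> np.ndarray:
    return 10.0 ** np.arange(lo_exp, hi_exp + 1, dtype=float)


@dataclass
class GridSearchConfig:
    """Grid-search and split settings for :func:`train_and_evaluate`.

    Defaults step the kernel width through the decades 1e-9..1e3 and the
    soft-margin cost through 1e-1..1e13. The number of cross-validation
    folds is not fixed by the protocol; 5-fold stratified is the default.
    """

    gamma_values: np.ndarray = field(default_factory=lambda: _decades(-9, 3))
    cost_values: np.ndarray = field(default_factory=lambda: _decades(-1, 13))
    n_folds: int = 5
    train_fraction: float = 0.6
    seed: int = 0
    #: hard cap on solver iterations — the large-cost corner of the grid
    #: does not converge on overlapping classes and would stall otherwise
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        self.gamma_values = np.asarray(self.gamma_values, dtype=float)
        self.cost_values = np.asarray(self.cost_values, dtype=float)
        if self.gamma_values.size == 0 or self.cost_values.size == 0:
            raise ValueError("parameter sequences must be nonempty")
        if np.any(np.diff(self.gamma_values) <= 0) or np.any(
            np.diff(self.cost_values) <= 0
        ):
            raise ValueError("parameter sequences must be strictly increasing")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ROCResult:
    """Held-out test performance of one trained classifier."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    f1_score: float
    best_gamma: float
    best_cost: float
    feature_subset: tuple[str, ...]


def train_and_evaluate(
    table: pd.DataFrame,
    feature_subset: Sequence[str],
    config: GridSearchConfig | None = None,
    labels: Sequence[bool] | None = None,
) -> ROCResult:
    """Grid-searched RBF-SVM evaluation of one feature subset.

    Labels default to :func:`gold_standard_labels` on the table. The data
    are split stratified 60/40 by the config seed; features are z-scored on
    the training split; every (gamma, cost) pair is scored by k-fold
    cross-validated accuracy on the training split with shared folds; the
    best pair is refit and evaluated on the test split (ROC over the
    decision-value sweep, trapezoidal AUC, f1 at decision value 0 with the
    diseased class positive).
    """
    config = config or GridSearchConfig()
    feature_subset = tuple(feature_subset)
    if not feature_subset:
        raise ValueError("feature_subset must be nonempty")
    y = (
        gold_standard_labels(table).to_numpy()
        if labels is None
        else np.asarray(labels, dtype=bool)
    )
    X = table.loc[:, list(feature_subset)].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in the labels")
    counts = np.bincount(y.astype(int))
    if counts.min() < 4:
        raise ValueError("need at least 4 samples per class")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=config.train_fraction,
        stratify=y,
        random_state=config.seed,
    )
    if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
        raise ValueError(
            "a class is absent from the train or test split; "
            "use a different seed or a larger cohort"
        )

    scaler = StandardScaler().fit(X_tr)
    X_tr_s = scaler.transform(X_tr)
    X_te_s = scaler.transform(X_te)

    folds = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    best = (-np.inf, np.nan, np.nan)
    for gamma in config.gamma_values:
        for cost in config.cost_values:
            clf = SVC(kernel="rbf", gamma=gamma, C=cost, max_iter=config.max_iter)
            acc = cross_val_score(clf, X_tr_s, y_tr, cv=folds, scoring="accuracy")
            score = float(acc.mean())
            if score > best[0]:
                best = (score, float(gamma), float(cost))
    _, best_gamma, best_cost = best

    clf = SVC(
        kernel="rbf", gamma=best_gamma, C=best_cost, max_iter=config.max_iter
    ).fit(X_tr_s, y_tr)
    scores = clf.decision_function(X_te_s)
    fpr, tpr, thresholds = roc_curve(y_te, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    f1 = float(f1_score(y_te, scores > 0, zero_division=0))
    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        f1_score=f1,
        best_gamma=best_gamma,
        best_cost=best_cost,
        feature_subset=feature_subset,
    )


def best_feature_combination(
    table: pd.DataFrame,
    feature_pool: Sequence[str],
    config: GridSearchConfig | None = None,
    labels: Sequence[bool] | None = None,
) -> list[tuple[tuple[str, ...], float, float]]:
    """Evaluate every nonempty feature subset under a shared split.

    Returns ``(subset, AUC, f1)`` tuples sorted by AUC then f1, descending.
    The pool is capped at 10 features (2^k - 1 subsets are evaluated
    exhaustively); pass an explicit subset list for larger pools.
    """
    pool = list(feature_pool)
    if len(pool) > 10:
        raise ValueError(
            "feature pool too large for exhaustive search; "
            "evaluate explicit subsets with train_and_evaluate instead"
        )
    if not pool:
        raise ValueError("feature pool must be nonempty")
    config = config or GridSearchConfig()
    results = []
    for k in range(1, len(pool) + 1):
        for subset in itertools.combinations(pool, k):
            res = train_and_evaluate(table, subset, config=config, labels=labels)
            results.append((subset, res.auc, res.f1_score))
    results.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return results
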