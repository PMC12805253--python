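"""Recursive feature elimination with cross-validation over gene features.

Each round fits the estimator on the current feature set, ranks features by
per-feature importance (sum over classes of absolute coefficients for the
linear model; impurity importance for the tree ensemble), drops the lowest
``ceil(step_fraction * remaining)``, and records the mean stratified
cross-validated score of the set. The returned selection is the evaluated
feature set with maximal mean CV score, ties broken toward fewer features.

Model fitting and scoring go through scikit-learn; the elimination schedule,
score path, ranking and tie-break are this module's contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .io import CNAMatrix, LabeledCohort
from .utils import logger


@dataclass
class RFECVConfig:
    estimator: Literal["linear_multiclass", "tree_ensemble"] = "linear_multiclass"
    scoring: Literal["accuracy", "balanced_accuracy"] = "balanced_accuracy"
    n_folds: int = 5
    step_fraction: float = 0.1
    min_features: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.step_fraction < 1:
            raise ValueError("step_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")

    def make_estimator(self):
        if self.estimator == "linear_multiclass":
            return LogisticRegression(max_iter=2000, random_state=self.seed)
        if self.estimator == "tree_ensemble":
            return RandomForestClassifier(n_estimators=100, random_state=self.seed)
        raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class RFECVResult:
    selected_genes: list[str]
    score_path: list[tuple[int, float]]  # (n_features, mean CV score), in elimination order
    ranking: dict[str, int]  # gene -> elimination round (kept genes share the final rank)
    path_sets: list[list[str]] = field(default_factory=list)  # feature set per path entry


def _importances(est, n_features: int) -> np.ndarray:
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_)
    coef = np.atleast_2d(est.coef_)
    return np.abs(coef).sum(axis=0)


def rfecv_select(cohort: LabeledCohort, config: RFECVConfig) -> RFECVResult:
    """Run the elimination path and return the best-scoring feature set."""
    X = cohort.matrix.values.astype(float)
    y = cohort.y
    genes = list(cohort.matrix.gene_ids)
    counts = np.bincount(y, minlength=cohort.n_classes)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"every class needs >= n_folds={config.n_folds} samples "
            f"(smallest class has {counts.min()})"
        )
    cv = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)

    current = list(range(len(genes)))
    if config.min_features >= len(genes):
        logger.warning("min_features >= feature count; selection is a no-op")
        score = float(np.mean(cross_val_score(
            config.make_estimator(), X, y, cv=cv, scoring=config.scoring)))
        return RFECVResult(list(genes), [(len(genes), score)],
                           {g: 1 for g in genes}, [list(genes)])

    score_path: list[tuple[int, float]] = []
    path_sets: list[list[str]] = []
    ranking: dict[str, int] = {}
    round_no = 1
    while True:
        Xc = X[:, current]
        score = float(np.mean(cross_val_score(
            config.make_estimator(), Xc, y, cv=cv, scoring=config.scoring)))
        score_path.append((len(current), score))
        path_sets.append([genes[j] for j in current])
        if len(current) <= config.min_features:
            break
        est = config.make_estimator().fit(Xc, y)
        imp = _importances(est, len(current))
        n_drop = min(math.ceil(config.step_fraction * len(current)),
                     len(current) - config.min_features)
        # lowest-importance features go; stable order for reproducible ties
        order = np.argsort(imp, kind="stable")
        drop_local = set(order[:n_drop].tolist())
        for j_local in sorted(drop_local):
            ranking[genes[current[j_local]]] = round_no
        current = [j for k, j in enumerate(current) if k not in drop_local]
        round_no += 1
    for j in current:
        ranking[genes[j]] = round_no

    # argmax mean CV score; ties toward fewer features
    best = max(range(len(score_path)),
               key=lambda i: (score_path[i][1], -score_path[i][0]))
    return RFECVResult(path_sets[best], score_path, ranking, path_sets)


def apply_selection(matrix: CNAMatrix, selected_genes: list[str]) -> CNAMatrix:
    """Column-subset a matrix to the selected genes, in the given order."""
    return matrix.subset_genes(selected_genes)
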