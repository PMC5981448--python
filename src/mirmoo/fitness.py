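"""Objective evaluation of candidate signatures.

A candidate miRNA subset is scored by (i) its cross-validated misclassification
rate under a pluggable classifier and (ii) the reciprocal of its aggregate
functional relevance; a tri-objective mode adds the subset size. All objectives
are minimised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .preprocess import ExpressionMatrix, SampleLabels
from .regnet import FRTable


class FitnessError(ValueError):
    pass


@dataclass
class CVConfig:
    """Inner cross-validation protocol for the error objective."""

    folds: int = 5
    inner_repeats: int = 3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise FitnessError("folds must be >= 2")


@dataclass
class ClassifierSpec:
    """Classifier family and hyperparameters; deterministic under seed.

    Families: ``svm`` (linear kernel, C=1 — the default), ``rf`` (random
    forest) and ``adaboost`` (decision stumps as weak learners). Features are
    standardised inside each training fold to keep Cq scales comparable for
    margin classifiers without leaking held-out statistics.
    """

    family: str = "svm"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def build(self) -> Pipeline:
        if self.family == "svm":
            clf = SVC(kernel="linear", C=1.0, random_state=self.seed, **self.params)
        elif self.family == "rf":
            clf = RandomForestClassifier(random_state=self.seed, **self.params)
        elif self.family == "adaboost":
            clf = AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                random_state=self.seed,
                **self.params,
            )
        else:
            raise FitnessError(f"unknown classifier family {self.family!r}")
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _design(subset, mat: ExpressionMatrix, labels: SampleLabels):
    subset = list(subset)
    if not subset:
        raise FitnessError("empty signature")
    missing = [m for m in subset if m not in mat.mirna_ids]
    if missing:
        raise FitnessError(f"signature miRNAs absent from matrix: {missing}")
    idx = [mat.mirna_ids.index(m) for m in subset]
    X = mat.values[idx].T  # samples x features
    if np.isnan(X).any():
        raise FitnessError("matrix must be imputed before fitness evaluation")
    return X, labels.y


def estimate_error(
    subset,
    mat: ExpressionMatrix,
    labels: SampleLabels,
    clf: ClassifierSpec | None = None,
    cv: CVConfig | None = None,
) -> float:
    """Mean held-out misclassification fraction over repeated stratified k-fold CV.

    Folds depend only on the CV seed and the labels, so the estimate is
    invariant to sample order and reproducible.
    """
    clf = clf or ClassifierSpec()
    cv = cv or CVConfig()
    X, y = _design(subset, mat, labels)
    if cv.stratified:
        splitter = RepeatedStratifiedKFold(
            n_splits=cv.folds, n_repeats=cv.inner_repeats, random_state=cv.seed
        )
    else:
        from sklearn.model_selection import RepeatedKFold

        splitter = RepeatedKFold(
            n_splits=cv.folds, n_repeats=cv.inner_repeats, random_state=cv.seed
        )
    # sort samples by (label, values) so the fold assignment depends on
    # content, not on input order
    order = np.lexsort((*X.T[::-1], y))
    X, y = X[order], y[order]
    errs = []
    for train, test in splitter.split(X, y):
        model = clf.build()
        model.fit(X[train], y[train])
        errs.append(float(np.mean(model.predict(X[test]) != y[test])))
    return float(np.mean(errs))


def signature_fr(subset, fr_tab: FRTable, mode: str = "sum") -> float:
    """Aggregate functional relevance of a signature.

    The aggregate is the sum of member FR scores by default; a mean mode is
    provided for sensitivity analyses. Always positive.
    """
    subset = list(subset)
    if not subset:
        raise FitnessError("empty signature")
    unknown = [m for m in subset if m not in fr_tab]
    if unknown:
        raise FitnessError(f"miRNAs absent from FR table: {unknown}")
    total = sum(fr_tab[m] for m in subset)
    if mode == "sum":
        return total
    if mode == "mean":
        return total / len(subset)
    raise FitnessError(f"unknown FR aggregation mode {mode!r}")


def objective_vector(
    subset,
    mat: ExpressionMatrix,
    labels: SampleLabels,
    fr_tab: FRTable,
    clf: ClassifierSpec | None = None,
    cv: CVConfig | None = None,
    k: int = 2,
    fr_mode: str = "sum",
) -> tuple[float, ...]:
    """(error, 1/FR) for k=2; (error, 1/FR, size) for k=3. All minimised."""
    if k not in (2, 3):
        raise FitnessError("k must be 2 or 3")
    err = estimate_error(subset, mat, labels, clf, cv)
    inv_fr = 1.0 / signature_fr(subset, fr_tab, mode=fr_mode)
    if k == 2:
        return (err, inv_fr)
    return (err, inv_fr, float(len(list(subset))))


def make_evaluator(
    candidate_ids,
    mat: ExpressionMatrix,
    labels: SampleLabels,
    fr_tab: FRTable,
    clf: ClassifierSpec | None = None,
    cv: CVConfig | None = None,
    k: int = 2,
    fr_mode: str = "sum",
):
    """Bind data and config into a bit-vector evaluator for the optimiser."""
    ids = np.asarray(list(candidate_ids), dtype=object)

    def evaluator(bits: np.ndarray):
        subset = list(ids[np.asarray(bits, dtype=bool)])
        return objective_vector(subset, mat, labels, fr_tab, clf, cv, k=k, fr_mode=fr_mode)

    return evaluator
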