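"""Outer discovery/validation harness, metrics, stability and significance.

The discovery loop mirrors the repeated-cross-validation design of the study:
samples are split into discovery and validation portions with stratified
k-fold CV, the multi-objective optimiser selects signatures on the discovery
portion only, a classifier is refit on that portion with the chosen signature,
and held-out performance is recorded. 'Long survival' is the positive class:
sensitivity is the hit rate on long survivors, specificity on short survivors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from sklearn.model_selection import StratifiedKFold

from .fitness import ClassifierSpec, CVConfig, make_evaluator, signature_fr
from .moo import GAConfig, evolve
from .preprocess import LONG, ExpressionMatrix, SampleLabels
from .regnet import FRTable

logger = logging.getLogger(__name__)


class EvaluateError(ValueError):
    pass


def performance_metrics(predicted, truth, positive: str = LONG):
    """(accuracy, sensitivity, specificity) with 'long survival' positive.

    sensitivity = TP/(TP+FN) on the positive class; specificity = TN/(TN+FP)
    on the other class. A metric whose class is absent from the truth is NaN.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise EvaluateError("predicted/truth length mismatch")
    correct = predicted == truth
    accuracy = float(correct.mean())
    pos = truth == positive
    neg = ~pos
    sensitivity = float(correct[pos].mean()) if pos.any() else float("nan")
    specificity = float(correct[neg].mean()) if neg.any() else float("nan")
    return accuracy, sensitivity, specificity


def jaccard(a, b) -> float:
    """Intersection over union; 1.0 by convention when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        logger.warning("Jaccard of two empty sets; returning 1.0 by convention")
        return 1.0
    return len(a & b) / len(a | b)


def stability(signatures) -> float:
    """Mean pairwise Jaccard index across a collection of signatures."""
    sigs = [set(s) for s in signatures]
    if len(sigs) < 2:
        raise EvaluateError("stability needs >= 2 signatures")
    pairs = list(itertools.combinations(sigs, 2))
    return float(np.mean([jaccard(a, b) for a, b in pairs]))


def permutation_significance(
    signature,
    objective_fn,
    candidate_pool,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Nominal permutation p-value for a signature's objective vector.

    The observed vector and each of ``n_perm`` random same-size subsets of the
    candidate pool are scalarised by Euclidean distance to the origin (the
    ideal point); p is the fraction of null subsets at least as close. Zero is
    a legal nominal value.
    """
    pool = list(candidate_pool)
    signature = list(signature)
    if not set(signature) <= set(pool):
        raise EvaluateError("signature must be a subset of the candidate pool")
    if len(signature) > len(pool):
        raise EvaluateError("candidate pool smaller than the signature")
    if n_perm < 1:
        raise EvaluateError("n_perm must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)

    observed = float(np.linalg.norm(np.asarray(objective_fn(signature), dtype=float)))
    hits = 0
    for _ in range(n_perm):
        draw = list(rng.choice(pool, size=len(signature), replace=False))
        norm = float(np.linalg.norm(np.asarray(objective_fn(draw), dtype=float)))
        if norm <= observed:
            hits += 1
    return hits / n_perm


@dataclass
class RunResult:
    """One outer discovery/validation run."""

    signature: tuple[str, ...]
    objectives: tuple[float, ...]
    accuracy: float
    sensitivity: float
    specificity: float
    fr: float
    size: int
    front_size: int


def select_representative(front_objectives) -> int:
    """Index of the Pareto member with minimal first objective; ties broken
    lexicographically on the remaining objectives, then by index."""
    F = np.asarray(front_objectives, dtype=float)
    order = sorted(range(len(F)), key=lambda i: (*F[i], i))
    return order[0]


def cross_validated_discovery(
    mat: ExpressionMatrix,
    labels: SampleLabels,
    fr_tab: FRTable,
    ga_config: GAConfig | None = None,
    clf: ClassifierSpec | None = None,
    cv_inner: CVConfig | None = None,
    outer_folds: int = 5,
    outer_repeats: int = 10,
    k_objectives: int = 2,
    candidate_selector=None,
    seed: int = 0,
) -> list[RunResult]:
    """Repeated outer CV around the multi-objective signature search.

    Per outer split: (optionally) select candidate miRNAs on the discovery
    portion, run the evolutionary search with the inner-CV error objective
    computed on the discovery portion only, choose the representative Pareto
    member (minimal error), refit the classifier on the discovery portion and
    predict the held-out samples. Outer and inner randomness use independent
    seeded streams so inner repeats never perturb the outer fold layout.
    """
    ga_config = ga_config or GAConfig()
    clf = clf or ClassifierSpec()
    cv_inner = cv_inner or CVConfig()
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(outer_repeats)]

    results: list[RunResult] = []
    y = labels.y
    for rep, rep_seed in enumerate(rep_seeds):
        outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=rep_seed)
        for fold, (disc, held) in enumerate(outer.split(np.zeros(len(y)), y)):
            disc_mat = ExpressionMatrix(
                mat.mirna_ids, [mat.sample_ids[i] for i in disc], mat.values[:, disc]
            )
            disc_labels = labels.subset(disc)

            if candidate_selector is not None:
                candidates = list(candidate_selector(disc_mat, disc_labels))
                if not candidates:
                    raise EvaluateError(f"no candidate miRNAs on repeat {rep} fold {fold}")
            else:
                candidates = list(mat.mirna_ids)

            run_seed = int((rep_seed * outer_folds + fold) % (2**31))
            inner_cv = CVConfig(
                folds=cv_inner.folds,
                inner_repeats=cv_inner.inner_repeats,
                stratified=cv_inner.stratified,
                seed=run_seed,
            )
            evaluator = make_evaluator(
                candidates, disc_mat, disc_labels, fr_tab, clf, inner_cv, k=k_objectives
            )
            cfg = GAConfig(
                population_size=ga_config.population_size,
                crossover_rate=ga_config.crossover_rate,
                mutation_rate=ga_config.mutation_rate,
                max_generations=ga_config.max_generations,
                spread_tolerance=ga_config.spread_tolerance,
                pareto_fraction=ga_config.pareto_fraction,
                stall_window=ga_config.stall_window,
                init_prob=ga_config.init_prob,
                seed=run_seed,
            )
            front, _ = evolve(evaluator, len(candidates), cfg)
            rep_idx = select_representative(front.objectives)
            signature = front.selected(candidates)[rep_idx]

            model = clf.build()
            idx = [mat.mirna_ids.index(m) for m in signature]
            model.fit(mat.values[np.ix_(idx, disc)].T, labels.classes[disc])
            predicted = model.predict(mat.values[np.ix_(idx, held)].T)
            acc, sens, spec = performance_metrics(predicted, labels.classes[held])

            results.append(
                RunResult(
                    signature=tuple(signature),
                    objectives=tuple(front.objectives[rep_idx]),
                    accuracy=acc,
                    sensitivity=sens,
                    specificity=spec,
                    fr=signature_fr(signature, fr_tab),
                    size=len(signature),
                    front_size=len(front),
                )
            )
    return results


def summarize_runs(results: list[RunResult]) -> dict:
    """Mean +/- SD of the per-run metrics, plus signature stability."""
    if not results:
        raise EvaluateError("no runs to summarise")

    def ms(vals):
        arr = np.asarray(vals, dtype=float)
        return {"mean": float(np.nanmean(arr)), "sd": float(np.nanstd(arr))}

    out = {
        "n_runs": len(results),
        "accuracy": ms([r.accuracy for r in results]),
        "sensitivity": ms([r.sensitivity for r in results]),
        "specificity": ms([r.specificity for r in results]),
        "fr": ms([r.fr for r in results]),
        "size": ms([r.size for r in results]),
    }
    if len(results) >= 2:
        out["stability"] = stability([r.signature for r in results])
    return out
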