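"""Preprocessing of qPCR Cq expression matrices and survival metadata.

Turns raw cycle-quantification (Cq) tables into a filtered, quantile-normalised,
KNN-imputed expression matrix with a binary survival labelling, and derives
candidate miRNA lists from non-parametric differential expression and
``2^-ddCt`` fold changes. Lower Cq means higher abundance throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import nan_euclidean_distances

SHORT = "short"
LONG = "long"
#: 'long survival' is the positive class for sensitivity/specificity.
POSITIVE_CLASS = LONG


class PreprocessError(ValueError):
    """Raised when a preprocessing contract is violated."""


@dataclass
class ExpressionMatrix:
    """A miRNA-by-sample matrix of Cq values with explicit missingness.

    Missing entries are stored as NaN in ``values``; ``missing_mask`` is the
    derived boolean view. Row and column identifiers are ordered and unique.
    """

    mirna_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float64, NaN marks a missing measurement

    def __post_init__(self) -> None:
        self.mirna_ids = list(self.mirna_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise PreprocessError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.sample_ids)} samples"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise PreprocessError("duplicate miRNA identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PreprocessError("duplicate sample identifiers")
        observed = ~np.isnan(self.values)
        if not np.isfinite(self.values[observed]).all():
            raise PreprocessError("non-finite Cq value in observed entries")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.mirna_ids, self.sample_ids, self.values.copy())

    def row(self, mirna_id: str) -> np.ndarray:
        return self.values[self.mirna_ids.index(mirna_id)]

    def subset_mirnas(self, ids) -> "ExpressionMatrix":
        idx = [self.mirna_ids.index(m) for m in ids]
        return ExpressionMatrix(list(ids), self.sample_ids, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(dtype=float))


@dataclass
class SampleLabels:
    """Binary short/long survival labelling, optionally with survival months."""

    sample_ids: list[str]
    classes: np.ndarray  # array of SHORT / LONG strings
    survival_months: np.ndarray | None = None
    positive_class: str = field(default=POSITIVE_CLASS, init=False)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.classes = np.asarray(self.classes, dtype=object)
        if len(self.classes) != len(self.sample_ids):
            raise PreprocessError("labels/sample count mismatch")
        bad = set(self.classes) - {SHORT, LONG}
        if bad:
            raise PreprocessError(f"unknown class labels: {sorted(bad)}")
        if self.survival_months is not None:
            self.survival_months = np.asarray(self.survival_months, dtype=float)
            if len(self.survival_months) != len(self.sample_ids):
                raise PreprocessError("survival_months/sample count mismatch")

    @property
    def y(self) -> np.ndarray:
        """Integer view: 1 = positive (long survival), 0 = short."""
        return (self.classes == LONG).astype(int)

    def class_indices(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.classes == cls)

    def subset(self, idx) -> "SampleLabels":
        idx = np.asarray(idx)
        sm = None if self.survival_months is None else self.survival_months[idx]
        return SampleLabels([self.sample_ids[i] for i in idx], self.classes[idx], sm)


def filter_missing(mat: ExpressionMatrix, max_missing_frac: float = 0.5) -> ExpressionMatrix:
    """Drop miRNA rows missing in more than ``max_missing_frac`` of samples.

    A row is retained iff its missing fraction is <= the threshold; sample
    axis and row order are untouched.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise PreprocessError("max_missing_frac must be in [0, 1]")
    frac = mat.missing_mask.mean(axis=1)
    keep = frac <= max_missing_frac
    if not keep.any():
        raise PreprocessError(
            f"no miRNAs survive the missingness filter at {max_missing_frac:g}"
        )
    ids = [m for m, k in zip(mat.mirna_ids, keep) if k]
    return ExpressionMatrix(ids, mat.sample_ids, mat.values[keep])


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalise samples to a shared reference distribution.

    The reference is the across-sample mean of the per-sample empirical
    quantile functions; for complete data this is exactly the mean of sorted
    value vectors and every sample's sorted vector equals the reference
    afterwards. Missing entries are excluded from the reference and stay
    missing. Ties receive the value at their average rank.
    """
    if mat.n_samples < 2:
        raise PreprocessError("quantile normalisation needs at least 2 samples")
    X = mat.values
    n = mat.n_mirnas
    grid = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    qfuns = np.empty((mat.n_samples, len(grid)))
    for j in range(mat.n_samples):
        obs = np.sort(X[~np.isnan(X[:, j]), j])
        if obs.size == 0:
            raise PreprocessError(f"sample {mat.sample_ids[j]!r} has no observed values")
        if obs.size == 1:
            qfuns[j] = obs[0]
        else:
            qfuns[j] = np.interp(grid, np.linspace(0.0, 1.0, obs.size), obs)
    ref = qfuns.mean(axis=0)

    out = np.full_like(X, np.nan)
    for j in range(mat.n_samples):
        oi = np.flatnonzero(~np.isnan(X[:, j]))
        m = oi.size
        ranks = stats.rankdata(X[oi, j], method="average")
        pos = (ranks - 1.0) / (m - 1.0) if m > 1 else np.array([0.5])
        out[oi, j] = np.interp(pos, grid, ref)
    return ExpressionMatrix(mat.mirna_ids, mat.sample_ids, out)


def knn_impute(mat: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Impute missing Cq values from the k nearest miRNA rows.

    Row-to-row distances are Euclidean over co-observed samples, scaled up by
    the proportion of samples co-observed (the KNNimpute convention). A missing
    cell takes the unweighted mean of the k nearest rows that are observed at
    that sample; rows with no co-observed samples are not eligible donors.
    """
    if k < 1:
        raise PreprocessError("k must be >= 1")
    X = mat.values
    fully_missing = np.isnan(X).all(axis=1)
    if fully_missing.any():
        bad = [mat.mirna_ids[i] for i in np.flatnonzero(fully_missing)]
        raise PreprocessError(f"fully missing miRNA rows cannot be imputed: {bad}")
    if not np.isnan(X).any():
        return mat.copy()

    D = nan_euclidean_distances(X)  # NaN where rows share no observed sample
    np.fill_diagonal(D, np.inf)
    D[np.isnan(D)] = np.inf

    out = X.copy()
    rows, cols = np.nonzero(np.isnan(X))
    for i, j in zip(rows, cols):
        donors = np.flatnonzero(~np.isnan(X[:, j]) & np.isfinite(D[i]))
        if donors.size == 0:
            raise PreprocessError(
                f"no eligible donor rows for {mat.mirna_ids[i]!r} "
                f"at sample {mat.sample_ids[j]!r}"
            )
        # stable sort: ties broken by row index, deterministically
        order = donors[np.argsort(D[i, donors], kind="stable")]
        out[i, j] = X[order[:k], j].mean()
    return ExpressionMatrix(mat.mirna_ids, mat.sample_ids, out)


def dichotomize_survival(
    sample_ids,
    survival_months,
    alive_at_followup=None,
    cutoff_months: float = 24.0,
) -> SampleLabels:
    """Dichotomise survival into short (< cutoff) vs long (>= cutoff).

    Patients alive at the end of follow-up are labelled long survival
    regardless of their observed time. Survival exactly at the cutoff is long.
    """
    if cutoff_months <= 0:
        raise PreprocessError("cutoff must be positive")
    months = np.asarray(survival_months, dtype=float)
    if (months < 0).any():
        raise PreprocessError("negative survival time")
    classes = np.where(months < cutoff_months, SHORT, LONG).astype(object)
    if alive_at_followup is not None:
        alive = np.asarray(alive_at_followup, dtype=bool)
        classes[alive] = LONG
    return SampleLabels(list(sample_ids), classes, months)


def smote_oversample(
    mat: ExpressionMatrix,
    labels: SampleLabels,
    k: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, SampleLabels]:
    """Double the minority class with SMOTE-style synthetic samples.

    One synthetic sample is created per minority sample, placed uniformly on
    the segment to one of its k nearest minority neighbours (Euclidean over
    miRNAs). Requires a complete (imputed) matrix. Majority samples are
    untouched; the majority class is not undersampled.
    """
    if np.isnan(mat.values).any():
        raise PreprocessError("SMOTE requires a complete (imputed) matrix")
    rng = rng if rng is not None else np.random.default_rng(seed)

    counts = {c: int((labels.classes == c).sum()) for c in (SHORT, LONG)}
    minority = min(counts, key=counts.get)
    min_idx = labels.class_indices(minority)
    n_min = min_idx.size
    if n_min < 2:
        raise PreprocessError("minority class needs >= 2 samples for SMOTE")
    k_eff = min(k, n_min - 1)

    P = mat.values[:, min_idx].T  # minority samples x miRNAs
    d = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)

    synth = np.empty((n_min, mat.n_mirnas))
    for i in range(n_min):
        nbrs = np.argsort(d[i], kind="stable")[:k_eff]
        nb = nbrs[rng.integers(k_eff)]
        u = rng.random()
        synth[i] = P[i] + u * (P[nb] - P[i])

    new_ids = [f"synthetic_{minority}_{i + 1}" for i in range(n_min)]
    values = np.hstack([mat.values, synth.T])
    out_mat = ExpressionMatrix(mat.mirna_ids, mat.sample_ids + new_ids, values)
    classes = np.concatenate([labels.classes, np.array([minority] * n_min, dtype=object)])
    sm = None
    if labels.survival_months is not None:
        sm = np.concatenate([labels.survival_months, np.full(n_min, np.nan)])
    return out_mat, SampleLabels(out_mat.sample_ids, classes, sm)


def differential_expression(
    mat: ExpressionMatrix, labels: SampleLabels, method: str = "ks"
) -> pd.Series:
    """Two-sided per-miRNA p-values for short vs long Cq distributions.

    ``method`` is ``"ks"`` (two-sample Kolmogorov-Smirnov) or ``"wilcoxon"``
    (rank-sum / Mann-Whitney U, exact for small tie-free samples). A miRNA
    with fewer than 2 observed values in either class gets NaN rather than
    being dropped.
    """
    if method not in ("ks", "wilcoxon"):
        raise PreprocessError(f"unknown test {method!r}")
    si, li = labels.class_indices(SHORT), labels.class_indices(LONG)
    if si.size == 0 or li.size == 0:
        raise PreprocessError("both classes must be non-empty")
    pvals = np.full(mat.n_mirnas, np.nan)
    for i in range(mat.n_mirnas):
        a = mat.values[i, si]
        b = mat.values[i, li]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            continue
        if method == "ks":
            p = stats.ks_2samp(a, b, alternative="two-sided").pvalue
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
        pvals[i] = min(p, 1.0)
    return pd.Series(pvals, index=mat.mirna_ids, name=f"p_{method}")


def fold_change(
    mat: ExpressionMatrix, labels: SampleLabels, short_over_long: bool = True
) -> pd.Series:
    """Per-miRNA ``2^-ddCt`` fold change between survival classes.

    With the default convention FC > 1 means higher expression (lower Cq) in
    the short-survival class; ``short_over_long=False`` flips the ratio. A
    class with no observed values yields NaN.
    """
    si, li = labels.class_indices(SHORT), labels.class_indices(LONG)
    with np.errstate(invalid="ignore"):
        m_short = np.nanmean(mat.values[:, si], axis=1) if si.size else np.full(mat.n_mirnas, np.nan)
        m_long = np.nanmean(mat.values[:, li], axis=1) if li.size else np.full(mat.n_mirnas, np.nan)
    ddct = m_short - m_long
    if not short_over_long:
        ddct = -ddct
    fc = np.power(2.0, -ddct)
    return pd.Series(fc, index=mat.mirna_ids, name="fold_change")


def candidate_filter(
    p_values: pd.Series | None,
    fold_changes: pd.Series | None,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> list[str]:
    """miRNAs passing p < p_cut and/or |fold change| beyond fc_cut either way.

    Either filter may be disabled by passing None for its input. Fold changes
    pass when FC > fc_cut or FC < 1/fc_cut. NaN never passes.
    """
    if p_values is None and fold_changes is None:
        raise PreprocessError("at least one of p_values / fold_changes required")
    if p_cut <= 0 or fc_cut <= 0:
        raise PreprocessError("thresholds must be positive")
    keep = None
    if p_values is not None:
        keep = (p_values < p_cut) & p_values.notna()
    if fold_changes is not None:
        fc_keep = ((fold_changes > fc_cut) | (fold_changes < 1.0 / fc_cut)) & fold_changes.notna()
        keep = fc_keep if keep is None else (keep & fc_keep)
    return list(keep.index[keep])
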