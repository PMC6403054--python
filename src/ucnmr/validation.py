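"""Ensemble validation: repeated external 10-fold cross-validation with
class-size correction, a matching permutation null, and their
Kolmogorov–Smirnov comparison.

Each repetition randomly undersamples the majority class to the minority
size (the "correction for unequal class sizes"), partitions the balanced set
into stratified external folds, fits the scaler and the O-PLS-DA model on
the training folds only (with its internal 7-fold sizing), and pools the
test-fold predictions of that repetition into one confusion matrix, yielding
one accuracy/sensitivity/specificity triple per repetition.  The permutation
null repeats the identical procedure with class labels randomly permuted
before balancing.  The two per-repetition metric distributions are compared
with the two-sided two-sample Kolmogorov–Smirnov test, significant at
p ≤ 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chemometrics import fit_oplsda, predict_oplsda
from .processing import BucketTable, pareto_scale

__all__ = [
    "CVPolicy",
    "EnsembleResult",
    "KSReport",
    "stratified_balanced_folds",
    "external_cv_ensemble",
    "permutation_null_ensemble",
    "ks_compare",
    "summarize_metric",
]


@dataclass(frozen=True)
class CVPolicy:
    external_k: int = 10
    n_repetitions: int = 1000
    internal_k: int = 7
    balance: str = "undersample"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.external_k < 2:
            raise ValueError("external_k must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class EnsembleResult:
    """Per-repetition classification metrics, in percent."""

    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    confusions: np.ndarray  # n_reps × 4: tp, tn, fp, fn
    policy: CVPolicy
    positive_label: str

    def metric(self, name: str) -> np.ndarray:
        if name not in ("accuracy", "sensitivity", "specificity"):
            raise ValueError(f"unknown metric {name!r}")
        return getattr(self, name)

    def summary(self) -> dict[str, str]:
        return {m: summarize_metric(self.metric(m))
                for m in ("accuracy", "sensitivity", "specificity")}


@dataclass(frozen=True)
class KSReport:
    statistic: float
    p_value: float
    significant: bool
    metric: str = "accuracy"


def _one_balanced_partition(
    labels: np.ndarray, external_k: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Undersample the majority class, then stratified k folds of the balanced set."""
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    m = int(counts.min())
    kept = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        kept.append(rng.choice(idx, size=m, replace=False))
    k = external_k
    if m < k:
        warnings.warn(
            f"minority class ({m}) smaller than external_k={external_k}; using {m} folds",
            stacklevel=3,
        )
        k = m
    folds: list[list[int]] = [[] for _ in range(k)]
    for idx in kept:
        shuffled = idx.copy()
        rng.shuffle(shuffled)
        for part, chunk in enumerate(np.array_split(shuffled, k)):
            folds[part].extend(chunk.tolist())
    kept_all = np.sort(np.concatenate(kept))
    return kept_all, [np.sort(np.array(f, dtype=int)) for f in folds]


def stratified_balanced_folds(labels, policy: CVPolicy, rng: np.random.Generator):
    """Yield (kept_indices, test_folds) for each repetition of the policy."""
    labels = np.asarray(labels).astype(str)
    for _ in range(policy.n_repetitions):
        yield _one_balanced_partition(labels, policy.external_k, rng)


def _ensemble(
    values: np.ndarray,
    labels: np.ndarray,
    policy: CVPolicy,
    rng: np.random.Generator,
    positive_label: str,
    permute: bool,
    bucket_centers: np.ndarray,
) -> EnsembleResult:
    n_reps = policy.n_repetitions
    acc = np.empty(n_reps)
    sens = np.empty(n_reps)
    spec = np.empty(n_reps)
    conf = np.empty((n_reps, 4), dtype=int)
    for r in range(n_reps):
        rep_labels = rng.permutation(labels) if permute else labels
        kept, folds = _one_balanced_partition(rep_labels, policy.external_k, rng)
        tp = tn = fp = fn = 0
        for test in folds:
            if test.size == 0:
                continue
            train = np.setdiff1d(kept, test)
            train_table = BucketTable(
                values=values[train],
                bucket_centers=bucket_centers,
                sample_ids=[str(i) for i in train],
            )
            scaled, scaler = pareto_scale(train_table)
            model = fit_oplsda(
                scaled,
                rep_labels[train],
                scaler=scaler,
                internal_k=policy.internal_k,
                rng=rng,
                positive_class=positive_label,
            )
            _, calls, _ = predict_oplsda(model, values[test])
            truth_pos = rep_labels[test] == positive_label
            call_pos = calls == positive_label
            tp += int(np.sum(truth_pos & call_pos))
            tn += int(np.sum(~truth_pos & ~call_pos))
            fp += int(np.sum(~truth_pos & call_pos))
            fn += int(np.sum(truth_pos & ~call_pos))
        total = tp + tn + fp + fn
        acc[r] = 100.0 * (tp + tn) / total
        sens[r] = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spec[r] = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        conf[r] = (tp, tn, fp, fn)
    return EnsembleResult(
        accuracy=acc, sensitivity=sens, specificity=spec,
        confusions=conf, policy=policy, positive_label=positive_label,
    )


def _as_values(table) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, BucketTable):
        if table.scaled:
            raise ValueError("pass the unscaled bucket table; scaling is fitted per fold")
        return table.values, table.bucket_centers
    values = np.asarray(table, dtype=float)
    return values, np.arange(values.shape[1], dtype=float)


def external_cv_ensemble(
    table,
    labels,
    policy: CVPolicy = CVPolicy(),
    rng: np.random.Generator | None = None,
    positive_label: str | None = None,
) -> EnsembleResult:
    """Repeated balanced external cross-validation of O-PLS-DA models.

    Scaling statistics and model sizing are computed inside each training
    split only, so every test fold is strictly blinded.
    """
    values, centers = _as_values(table)
    labels = np.asarray(labels).astype(str)
    rng = rng if rng is not None else np.random.default_rng(policy.seed)
    if positive_label is None:
        positive_label = sorted(np.unique(labels))[1]
    return _ensemble(values, labels, policy, rng, positive_label, permute=False,
                     bucket_centers=centers)


def permutation_null_ensemble(
    table,
    labels,
    policy: CVPolicy = CVPolicy(),
    rng: np.random.Generator | None = None,
    positive_label: str | None = None,
) -> EnsembleResult:
    """The identical CV procedure with labels randomly permuted per repetition."""
    values, centers = _as_values(table)
    labels = np.asarray(labels).astype(str)
    rng = rng if rng is not None else np.random.default_rng(policy.seed)
    if positive_label is None:
        positive_label = sorted(np.unique(labels))[1]
    return _ensemble(values, labels, policy, rng, positive_label, permute=True,
                     bucket_centers=centers)


def ks_compare(
    observed: EnsembleResult, null: EnsembleResult, metric: str = "accuracy"
) -> KSReport:
    """Two-sided two-sample Kolmogorov–Smirnov test on a per-repetition metric."""
    a = observed.metric(metric)
    b = null.metric(metric)
    if a.size < 10 or b.size < 10:
        raise ValueError("need at least 10 repetitions on each side")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    p = float(res.pvalue)
    return KSReport(statistic=float(res.statistic), p_value=p,
                    significant=p <= 0.05, metric=metric)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def summarize_metric(values) -> str:
    """Format a metric distribution as "mean ± SD%", both rounded half-up."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least 2 values to summarize")
    return f"{_round_half_up(values.mean())} ± {_round_half_up(values.std(ddof=1))}%"
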