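"""PCA and orthogonal projections to latent structures discriminant analysis.

The O-PLS implementation follows the classic NIPALS formulation for a
univariate response: the predictive weight vector ``w ∝ Xᵀy`` is invariant
under orthogonal deflation, each orthogonal component is extracted from the
part of the loading vector orthogonal to ``w``, and the final predictive
component is computed from the deflated matrix.  With zero orthogonal
components the model is exactly a one-component PLS1 regression.

The number of orthogonal components is sized by internal stratified 7-fold
cross-validation on Q²Y (1 − PRESS/TSS, TSS about the training-fold response
mean): components are added while Q² improves by more than 0.01 absolute,
capped at 9.  Class membership is encoded 0/1 and the decision threshold is
the midpoint of the training class-mean predicted responses, which for
balanced training sets sits at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .processing import BucketTable, ScalingModel

__all__ = [
    "PCAModel",
    "OPLSDAModel",
    "fit_pca",
    "fit_oplsda",
    "predict_oplsda",
    "compute_vip",
    "select_discriminatory_variables",
    "percent_difference",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    loadings: np.ndarray  # features × components, orthonormal columns
    scores: np.ndarray  # samples × components
    explained_variance_fraction: np.ndarray


def fit_pca(X, n_components: int) -> PCAModel:
    """Principal components via SVD of the column-centred matrix.

    Sign convention: within each component the largest-magnitude loading
    element is made positive, so fits are deterministic.
    """
    X = X.values if isinstance(X, BucketTable) else np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, features)={min(n - 1, p)}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:n_components].T.copy()
    scores = U[:, :n_components] * s[:n_components]
    for j in range(n_components):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total = float(np.sum(s**2))
    evf = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAModel(loadings=loadings, scores=scores, explained_variance_fraction=evf)


# ---------------------------------------------------------------------------
# O-PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OPLSDAModel:
    classes: tuple[str, str]  # encoded (0, 1); classes[1] is the positive class
    w: np.ndarray  # predictive weights, unit norm
    p: np.ndarray  # predictive loadings
    t: np.ndarray  # training predictive scores
    c: float  # class loading (regression of centred y on t)
    W_o: np.ndarray  # features × n_ortho orthogonal weights
    P_o: np.ndarray  # features × n_ortho orthogonal loadings
    n_ortho: int
    y_mean: float
    decision_threshold: float
    scaler: ScalingModel | None = None
    q2_trace: list[float] = field(default_factory=list)

    @property
    def y_encoding(self) -> dict[str, int]:
        return {self.classes[0]: 0, self.classes[1]: 1}


def _encode_labels(labels, positive_class: str | None) -> tuple[np.ndarray, tuple[str, str]]:
    labels = np.asarray(labels)
    classes = sorted(map(str, np.unique(labels)))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {classes}")
    if positive_class is not None:
        pos = str(positive_class)
        if pos not in classes:
            raise ValueError(f"positive class {pos!r} not among {classes}")
        classes = [c for c in classes if c != pos] + [pos]
    y = (labels.astype(str) == classes[1]).astype(float)
    return y, (classes[0], classes[1])


def _extract_ortho(X: np.ndarray, w: np.ndarray):
    """One orthogonal component (weight, score, loading) from the deflated X."""
    t = X @ w
    tt = float(t @ t)
    if tt <= 0:
        return None
    p = X.T @ t / tt
    w_o = p - float(w @ p) * w
    norm = float(np.linalg.norm(w_o))
    if norm < 1e-12:
        return None
    w_o /= norm
    t_o = X @ w_o
    tt_o = float(t_o @ t_o)
    if tt_o <= 0:
        return None
    p_o = X.T @ t_o / tt_o
    return w_o, t_o, p_o


def _fit_core(X: np.ndarray, yc: np.ndarray, n_ortho: int):
    """Fit O-PLS with a fixed number of orthogonal components on scaled X, centred y."""
    w = X.T @ yc
    norm = float(np.linalg.norm(w))
    if norm < 1e-12:
        raise ValueError("constant predictor matrix (or y uncorrelated with every column)")
    w /= norm
    Wo, Po = [], []
    Xd = X
    for _ in range(n_ortho):
        comp = _extract_ortho(Xd, w)
        if comp is None:
            break
        w_o, t_o, p_o = comp
        Wo.append(w_o)
        Po.append(p_o)
        Xd = Xd - np.outer(t_o, p_o)
    t = Xd @ w
    tt = float(t @ t)
    p = Xd.T @ t / tt
    c = float(yc @ t) / tt
    W_o = np.column_stack(Wo) if Wo else np.zeros((X.shape[1], 0))
    P_o = np.column_stack(Po) if Po else np.zeros((X.shape[1], 0))
    return w, p, t, c, W_o, P_o


def _filter_ortho(X: np.ndarray, W_o: np.ndarray, P_o: np.ndarray) -> np.ndarray:
    Xd = X.copy()
    for j in range(W_o.shape[1]):
        t_o = Xd @ W_o[:, j]
        Xd -= np.outer(t_o, P_o[:, j])
    return Xd


def _stratified_folds(y01: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random class-stratified partition into k test folds (index arrays)."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        for part, chunk in enumerate(np.array_split(idx, k)):
            folds[part].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _internal_q2(
    X: np.ndarray,
    y01: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_ortho: int,
    q2_tol: float,
) -> tuple[int, list[float]]:
    """Choose n_ortho by sequential internal CV: add while Q² gains > q2_tol."""
    folds = _stratified_folds(y01, k, rng)
    # per-fold state for incremental orthogonal extraction
    state = []
    for test in folds:
        train = np.setdiff1d(np.arange(y01.size), test)
        ytr = y01[train]
        ym = float(ytr.mean())
        yc = ytr - ym
        Xtr = X[train]
        w = Xtr.T @ yc
        norm = float(np.linalg.norm(w))
        if norm < 1e-12:
            continue
        w /= norm
        state.append({
            "Xtr": Xtr.copy(), "Xte": X[test].copy(), "yte": y01[test],
            "yc": yc, "ym": ym, "w": w, "tss": float(np.sum((y01[test] - ym) ** 2)),
        })
    if not state:
        return 0, []

    def q2_now() -> float:
        press = 0.0
        tss = 0.0
        for st in state:
            t = st["Xtr"] @ st["w"]
            tt = float(t @ t)
            if tt <= 0:
                continue
            c = float(st["yc"] @ t) / tt
            t_new = st["Xte"] @ st["w"]
            yhat = t_new * c + st["ym"]
            press += float(np.sum((st["yte"] - yhat) ** 2))
            tss += st["tss"]
        return 1.0 - press / tss if tss > 0 else -np.inf

    trace = [q2_now()]
    chosen = 0
    for n_o in range(1, max_ortho + 1):
        progressed = False
        for st in state:
            comp = _extract_ortho(st["Xtr"], st["w"])
            if comp is None:
                continue
            w_o, t_o, p_o = comp
            st["Xtr"] = st["Xtr"] - np.outer(t_o, p_o)
            t_o_new = st["Xte"] @ w_o
            st["Xte"] = st["Xte"] - np.outer(t_o_new, p_o)
            progressed = True
        if not progressed:
            break
        trace.append(q2_now())
        if trace[-1] > trace[-2] + q2_tol:
            chosen = n_o
        else:
            break
    return chosen, trace


def fit_oplsda(
    X,
    labels,
    scaler: ScalingModel | None = None,
    internal_k: int = 7,
    rng: np.random.Generator | None = None,
    n_ortho: int | None = None,
    max_ortho: int = 9,
    q2_tol: float = 0.01,
    positive_class: str | None = None,
) -> OPLSDAModel:
    """Fit an O-PLS-DA model on an already-scaled matrix.

    Parameters
    ----------
    X : ndarray or BucketTable
        Scaled (e.g. Pareto-scaled) training matrix.
    labels : array-like
        Two-class labels, one per row.
    scaler : ScalingModel, optional
        The scaler fitted on the training rows; stored so that
        :func:`predict_oplsda` can consume unscaled bucket rows.
    n_ortho : int, optional
        Force the number of orthogonal components instead of sizing by
        internal cross-validation.
    """
    X = X.values if isinstance(X, BucketTable) else np.asarray(X, dtype=float)
    y01, classes = _encode_labels(labels, positive_class)
    counts = [int((y01 == v).sum()) for v in (0.0, 1.0)]
    if min(counts) < 1:
        raise ValueError("both classes must be present")
    rng = rng if rng is not None else np.random.default_rng(0)

    q2_trace: list[float] = []
    if n_ortho is None:
        k = internal_k
        if min(counts) < k:
            k = max(2, min(counts))
            warnings.warn(
                f"smallest class has {min(counts)} members; internal CV reduced to {k} folds",
                stacklevel=2,
            )
        n_ortho, q2_trace = _internal_q2(X, y01, k, rng, max_ortho, q2_tol)

    yc = y01 - y01.mean()
    w, p, t, c, W_o, P_o = _fit_core(X, yc, n_ortho)
    y_mean = float(y01.mean())
    y_hat = t * c + y_mean
    m0 = float(y_hat[y01 == 0].mean())
    m1 = float(y_hat[y01 == 1].mean())
    return OPLSDAModel(
        classes=classes, w=w, p=p, t=t, c=c, W_o=W_o, P_o=P_o,
        n_ortho=W_o.shape[1], y_mean=y_mean,
        decision_threshold=(m0 + m1) / 2.0, scaler=scaler, q2_trace=q2_trace,
    )


def predict_oplsda(
    model: OPLSDAModel,
    X_new,
    borderline_margin: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict unscaled bucket rows: (continuous y-estimate, class call, borderline).

    Applies the stored scaler (if any), removes the orthogonal variation,
    projects onto the predictive component and thresholds the 0/1-scale
    estimate at the training decision threshold.  Samples whose estimate
    falls within ``borderline_margin`` of the threshold are flagged
    borderline (the threshold sits at 0.5 for balanced training classes).
    """
    X_new = X_new.values if isinstance(X_new, BucketTable) else np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.w.size:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} does not match model ({model.w.size})"
        )
    Xs = model.scaler.transform(X_new) if model.scaler is not None else X_new
    Xd = _filter_ortho(Xs, model.W_o, model.P_o)
    t_new = Xd @ model.w
    y_est = t_new * model.c + model.y_mean
    calls = np.where(y_est > model.decision_threshold, model.classes[1], model.classes[0])
    borderline = np.abs(y_est - model.decision_threshold) < borderline_margin
    return y_est, calls, borderline


def compute_vip(model: OPLSDAModel) -> np.ndarray:
    """Variable importance in projection over the single predictive component.

    With unit-norm weights this reduces to ``sqrt(p) · |w|``, which satisfies
    the VIP normalization identity mean(VIP²) = 1.
    """
    p = model.w.size
    return np.sqrt(p) * np.abs(model.w)


def _column_correlations(X: np.ndarray, t: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    denom = np.sqrt(np.sum(Xc**2, axis=0) * float(np.sum(tc**2)))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ tc) / denom
    return np.where(denom > 0, r, np.nan)


def select_discriminatory_variables(
    model: OPLSDAModel,
    table: BucketTable,
    labels,
    annotation: dict[str, int] | None = None,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
    case_class: str | None = None,
) -> pd.DataFrame:
    """Concretize "selected as a significant discriminator".

    A bucket is selected when its VIP exceeds 1 *and* its correlation
    loading — the Pearson correlation between the scaled bucket and the
    predictive score — is extreme at the two-sided 5% level against a
    label-permutation null (``n_boot`` resamples, each refitting the
    predictive direction on permuted labels; the reported ``null_lo``/
    ``null_hi`` band is its 95% envelope),
    *and* the sign of its between-group percent difference
    agrees with the correlation loading.  The permutation band, rather than
    a naive bootstrap interval of the in-sample correlation, is what keeps
    the selection calibrated: the predictive score is itself fitted to the
    labels, so its in-sample correlations are inflated under the null and a
    resampling interval around them would rarely cover zero.  Percent
    differences are computed on the unscaled bucket integrals.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if table.scaled:
        raise ValueError("pass the unscaled bucket table")
    n_buckets = table.values.shape[1]
    if annotation:
        bad = [name for name, idx in annotation.items() if not 0 <= idx < n_buckets]
        if bad:
            raise ValueError(f"annotation names unknown buckets: {bad}")
    labels = np.asarray(labels).astype(str)
    case = case_class if case_class is not None else model.classes[1]
    control = model.classes[0] if case != model.classes[0] else model.classes[1]

    Xs = np.asarray(
        model.scaler.transform(table.values) if model.scaler is not None else table.values,
        dtype=float,
    )
    Xd = _filter_ortho(Xs, model.W_o, model.P_o)
    t = Xd @ model.w
    r = _column_correlations(Xs, t)

    y01 = (labels == case).astype(float)
    nulls = np.empty((n_boot, n_buckets))
    for b in range(n_boot):
        yp = rng.permutation(y01)
        ypc = yp - yp.mean()
        w_b = Xs.T @ ypc
        norm = np.linalg.norm(w_b)
        if norm < 1e-12:
            nulls[b] = np.nan
            continue
        nulls[b] = _column_correlations(Xs, Xs @ (w_b / norm))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ci_lo = np.nanpercentile(nulls, 2.5, axis=0)
        ci_hi = np.nanpercentile(nulls, 97.5, axis=0)
        # two-sided permutation p-value, observed included (guarantees validity)
        n_extreme = np.nansum(np.abs(nulls) >= np.abs(r)[None, :], axis=0)
    perm_p = (1.0 + n_extreme) / (n_boot + 1.0)

    vip = compute_vip(model)
    case_mean = table.values[labels == case].mean(axis=0)
    ctrl_mean = table.values[labels == control].mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (case_mean - ctrl_mean) / ctrl_mean
    sign_ok = np.sign(pct) == np.sign(r)
    selected = (vip > 1.0) & (perm_p <= 0.05) & sign_ok

    metabolite = np.array([None] * n_buckets, dtype=object)
    if annotation:
        for name, idx in annotation.items():
            metabolite[idx] = name
    return pd.DataFrame({
        "bucket_center": table.bucket_centers,
        "vip": vip,
        "correlation": r,
        "null_lo": ci_lo,
        "null_hi": ci_hi,
        "perm_p": perm_p,
        "selected": selected,
        "metabolite": metabolite,
        "percent_difference": pct,
    })


def percent_difference(
    table: BucketTable,
    labels,
    target,
    annotation: dict[str, int] | None = None,
    case_label: str | None = None,
    control_label: str | None = None,
) -> float:
    """100 × (case mean − control mean) / control mean at one bucket.

    ``target`` may be a bucket index (int), a bucket-centre ppm (float) or an
    annotated metabolite name (str, requires ``annotation``).
    """
    if table.scaled:
        raise ValueError("percent differences are defined on unscaled bucket integrals")
    if isinstance(target, str):
        if annotation is None or target not in annotation:
            raise ValueError(f"no annotation for metabolite {target!r}")
        idx = annotation[target]
    elif isinstance(target, (int, np.integer)):
        idx = int(target)
    else:
        idx = int(np.argmin(np.abs(table.bucket_centers - float(target))))
    labels = np.asarray(labels).astype(str)
    classes = sorted(np.unique(labels))
    if len(classes) != 2 and (case_label is None or control_label is None):
        raise ValueError("need exactly two classes or explicit case/control labels")
    case = case_label if case_label is not None else classes[1]
    control = control_label if control_label is not None else classes[0]
    case_vals = table.values[labels == case, idx]
    ctrl_vals = table.values[labels == control, idx]
    if case_vals.size == 0 or ctrl_vals.size == 0:
        raise ValueError("both groups must be non-empty")
    ctrl_mean = float(ctrl_vals.mean())
    if ctrl_mean == 0:
        raise ValueError("control mean is zero; percent difference undefined")
    return 100.0 * (float(case_vals.mean()) - ctrl_mean) / ctrl_mean
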