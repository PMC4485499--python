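"""Projection models for spectral class discrimination, implemented from
scratch with NIPALS.

Provides PLS-DA (partial least squares regression onto class coding) with
R2X/R2Y, stratified k-fold cross-validated Q2, label-permutation validation,
OPLS-DA (predictive component plus class-orthogonal components), and
per-variable correlation/covariance loading profiles with noise-region
zeroing — the quantities behind score plots, |r|-coded loading plots and
R2/Q2 model summaries in NMR metabolomics.

Class coding: binary problems use a single 0/1 column, multi-class uses
one-hot; Y is always column-centered before fitting. X scaling defaults to
mean-centering so back-scaled covariance loadings retain spectral shape;
unit-variance and Pareto scaling are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 5000  # multi-Y fits with close eigenvalues converge slowly


# ---------------------------------------------------------------------------
# scaling

@dataclass
class ScalingParams:
    """Column centering/scaling parameters with an exact inverse."""

    method: str
    means: np.ndarray
    scales: np.ndarray
    constant_columns: np.ndarray  # bool flags; their divisor is 1

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.scales

    def invert(self, X_scaled: np.ndarray) -> np.ndarray:
        return X_scaled * self.scales + self.means


def scale_columns(X: np.ndarray, method: str = "center") -> tuple[np.ndarray, ScalingParams]:
    """Center (``center``), unit-variance (``uv``) or Pareto (``pareto``)
    scale the columns of X. Constant columns get divisor 1 and a flag."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    constant = sd == 0
    if method == "center":
        scales = np.ones_like(sd)
    elif method == "uv":
        scales = np.where(constant, 1.0, sd)
    elif method == "pareto":
        scales = np.where(constant, 1.0, np.sqrt(sd))
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    params = ScalingParams(method=method, means=means, scales=scales, constant_columns=constant)
    return params.apply(X), params


# ---------------------------------------------------------------------------
# class coding

def encode_labels(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """0/1 column for binary labels, one-hot for multi-class.

    Classes are sorted; for binary problems the second class codes 1.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if len(classes) == 2:
        Y = (labels == classes[1]).astype(float)[:, None]
    else:
        Y = np.column_stack([(labels == c).astype(float) for c in classes])
    return Y, classes


# ---------------------------------------------------------------------------
# PLS-DA

@dataclass
class PlsModel:
    """NIPALS PLS-DA fit: scores T, loadings P, weights W, y-weights C."""

    T: np.ndarray  # n x k scores
    P: np.ndarray  # p x k x-loadings
    W: np.ndarray  # p x k x-weights, unit norm columns
    C: np.ndarray  # m x k y-weights
    n_components: int
    r2x: float
    r2y: float
    r2x_per_component: np.ndarray
    r2y_per_component: np.ndarray
    x_scaling: ScalingParams
    y_means: np.ndarray
    classes: list
    labels_name: str = "class"

    def predict_scores(self, X_new: np.ndarray) -> np.ndarray:
        Xs = self.x_scaling.apply(np.asarray(X_new, dtype=float))
        w_star = self.W @ np.linalg.inv(self.P.T @ self.W)
        return Xs @ w_star

    def predict_y(self, X_new: np.ndarray) -> np.ndarray:
        """Predicted class coding (original 0/1 or one-hot scale)."""
        return self.predict_scores(X_new) @ self.C.T + self.y_means


def fit_plsda(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int = 2,
    scaling: str = "center",
) -> PlsModel:
    """Fit PLS-DA by NIPALS.

    Per component: w ∝ X'u (unit norm), t = Xw, c = Y't/(t't), u = Yc/(c'c),
    iterated to tolerance; X and Y are deflated by t. R2X/R2Y are fractions of
    scaled-X / centered-Y sum of squares explained by the k components.
    """
    X = np.asarray(X, dtype=float)
    Y0, classes = encode_labels(labels)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound min(n-1, p)={min(n - 1, p)}"
        )
    Xs, params = scale_columns(X, scaling)
    if not np.any(Xs != 0):
        raise ValueError("X has zero variance after scaling")
    y_means = Y0.mean(axis=0)
    Y = Y0 - y_means

    ssx0 = np.sum(Xs**2)
    ssy0 = np.sum(Y**2)
    Xd, Yd = Xs.copy(), Y.copy()
    Ts, Ps, Ws, Cs = [], [], [], []
    r2x_comp, r2y_comp = [], []
    for k in range(n_components):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if not np.any(u):
            u = Yd[:, 0] + 1.0  # degenerate Y residual; fall back to constant start
        t_old = None
        for _ in range(NIPALS_MAX_ITER):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(f"component {k + 1}: zero weight vector (X exhausted)")
            w /= nw
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                raise ValueError(f"component {k + 1}: zero score vector")
            c = Yd.T @ t / tt
            u = Yd @ c / (c @ c)
            if t_old is not None and np.linalg.norm(t - t_old) <= NIPALS_TOL * np.linalg.norm(t):
                t_old = t
                break
            t_old = t
        else:
            raise RuntimeError(f"NIPALS did not converge for component {k + 1}")
        t = t_old
        tt = t @ t
        p_load = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, c)
        Ts.append(t)
        Ps.append(p_load)
        Ws.append(w)
        Cs.append(c)
        r2x_comp.append(tt * (p_load @ p_load) / ssx0)
        r2y_comp.append(tt * (c @ c) / ssy0 if ssy0 > 0 else 0.0)

    return PlsModel(
        T=np.column_stack(Ts),
        P=np.column_stack(Ps),
        W=np.column_stack(Ws),
        C=np.column_stack(Cs),
        n_components=n_components,
        r2x=float(1.0 - np.sum(Xd**2) / ssx0),
        r2y=float(1.0 - np.sum(Yd**2) / ssy0) if ssy0 > 0 else 0.0,
        r2x_per_component=np.array(r2x_comp),
        r2y_per_component=np.array(r2y_comp),
        x_scaling=params,
        y_means=y_means,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    """Cross-validation and permutation-test summary for one model."""

    q2: float
    r2y: float
    press_per_fold: np.ndarray
    n_folds: int
    n_components: int
    seed: int
    perm_r2y: np.ndarray = field(default_factory=lambda: np.array([]))
    perm_q2: np.ndarray = field(default_factory=lambda: np.array([]))
    p_r2y: float | None = None
    p_q2: float | None = None
    n_permutations: int = 0

    def to_jsonable(self) -> dict:
        return {
            "q2": self.q2,
            "r2y": self.r2y,
            "n_folds": self.n_folds,
            "n_components": self.n_components,
            "n_permutations": self.n_permutations,
            "p_r2y": self.p_r2y,
            "p_q2": self.p_q2,
            "seed": self.seed,
        }


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment: within each class, indices
    are shuffled by the seeded RNG and dealt round-robin across folds."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for c in sorted(set(labels.tolist())):
        idx = np.nonzero(labels == c)[0]
        if len(idx) < n_folds:
            log.warning(
                "class %r has %d members < %d folds; stratification relaxed", c, len(idx), n_folds
            )
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % n_folds
    return folds


def cross_validated_q2(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int = 2,
    n_folds: int = 8,
    scaling: str = "center",
    seed: int = 0,
) -> ValidationReport:
    """Stratified k-fold Q2 = 1 - PRESS/TSS for a PLS-DA model.

    Scaling and the Y center are refit inside each training fold; TSS uses
    the training-fold Y mean as the naive predictor.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    Y_all, classes = encode_labels(labels)
    folds = stratified_folds(labels, n_folds, seed)
    press = np.zeros(n_folds)
    tss = np.zeros(n_folds)
    for f in range(n_folds):
        test = folds == f
        train = ~test
        if not test.any():
            continue
        if len(set(labels[train].tolist())) < 2:
            raise ValueError(
                f"fold {f}: training split has a single class; use fewer folds"
            )
        model = fit_plsda(X[train], labels[train], n_components=n_components, scaling=scaling)
        # coded Y on the full class set so folds are comparable
        y_train_mean = Y_all[train].mean(axis=0)
        y_hat = model.predict_scores(X[test]) @ model.C.T + model.y_means
        press[f] = np.sum((Y_all[test] - y_hat) ** 2)
        tss[f] = np.sum((Y_all[test] - y_train_mean) ** 2)
    full = fit_plsda(X, labels, n_components=n_components, scaling=scaling)
    q2 = float(1.0 - press.sum() / tss.sum())
    return ValidationReport(
        q2=q2,
        r2y=full.r2y,
        press_per_fold=press,
        n_folds=n_folds,
        n_components=n_components,
        seed=seed,
    )


def _distinct_label_arrangements(labels: np.ndarray) -> int:
    """Number of distinct label permutations: n! / prod(count_c!)."""
    counts = pd.Series(labels).value_counts()
    out = math.factorial(int(counts.sum()))
    for c in counts:
        out //= math.factorial(int(c))
    return out


def permutation_validate(
    X: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 999,
    n_components: int = 2,
    n_folds: int = 8,
    scaling: str = "center",
    seed: int = 0,
) -> ValidationReport:
    """Label-permutation null for R2Y and Q2.

    Labels are permuted uniformly; R2Y and Q2 are recomputed per permutation;
    empirical p = (1 + #{null >= observed}) / (1 + n_permutations). Degenerate
    designs with fewer than 20 distinct label arrangements are rejected.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be >= 20")
    labels = np.asarray(labels)
    if _distinct_label_arrangements(labels) < 20:
        raise ValueError(
            "too few distinct label arrangements for a permutation test; "
            "the null distribution would be degenerate"
        )
    rng = np.random.default_rng(seed)
    observed = cross_validated_q2(
        X, labels, n_components=n_components, n_folds=n_folds, scaling=scaling, seed=seed
    )
    perm_r2y = np.empty(n_permutations)
    perm_q2 = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = labels[rng.permutation(len(labels))]
        rep = cross_validated_q2(
            X, perm, n_components=n_components, n_folds=n_folds, scaling=scaling,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        perm_r2y[i] = rep.r2y
        perm_q2[i] = rep.q2
    p_r2y = float((1 + np.sum(perm_r2y >= observed.r2y)) / (1 + n_permutations))
    p_q2 = float((1 + np.sum(perm_q2 >= observed.q2)) / (1 + n_permutations))
    return ValidationReport(
        q2=observed.q2,
        r2y=observed.r2y,
        press_per_fold=observed.press_per_fold,
        n_folds=n_folds,
        n_components=n_components,
        seed=seed,
        perm_r2y=perm_r2y,
        perm_q2=perm_q2,
        p_r2y=p_r2y,
        p_q2=p_q2,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# OPLS-DA

@dataclass
class OplsModel:
    """OPLS-DA fit: one predictive component plus class-orthogonal components."""

    t_pred: np.ndarray  # (n,)
    p_pred: np.ndarray  # (p,)
    w_pred: np.ndarray  # (p,) unit norm
    c_pred: float
    T_ortho: np.ndarray  # n x j
    P_ortho: np.ndarray  # p x j
    W_ortho: np.ndarray  # p x j
    r2x_pred: float
    r2x_ortho: np.ndarray
    r2y: float
    covariance: np.ndarray  # per-variable cov(x, y)
    correlation: np.ndarray  # per-variable Pearson r(x, y)
    x_scaling: ScalingParams
    y_mean: float
    classes: list

    @property
    def n_orthogonal(self) -> int:
        return self.T_ortho.shape[1]

    @property
    def r2x(self) -> float:
        return float(self.r2x_pred + self.r2x_ortho.sum())


def fit_oplsda(
    X: np.ndarray,
    labels: np.ndarray,
    n_orthogonal: int = 1,
    scaling: str = "center",
) -> OplsModel:
    """Fit a two-class OPLS-DA model.

    Per orthogonal round on the current matrix: w ∝ X'y (unit norm), t = Xw,
    p = X't/(t't), orthogonal weight w_o ∝ p − (w'p)w (unit norm), t_o = Xw_o,
    p_o = X't_o/(t_o't_o), then X is deflated by t_o p_o'. The predictive
    component is a single-component PLS fit on the filtered matrix. The
    orthogonal scores are exactly uncorrelated with the class coding.
    """
    X = np.asarray(X, dtype=float)
    Y, classes = encode_labels(labels)
    if Y.shape[1] != 1:
        raise ValueError("OPLS-DA handles exactly 2 classes; use fit_plsda for more")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    y = Y[:, 0]
    y_mean = float(y.mean())
    yc = y - y_mean
    Xs, params = scale_columns(X, scaling)
    ssx0 = np.sum(Xs**2)
    if ssx0 == 0:
        raise ValueError("X has zero variance after scaling")

    Xd = Xs.copy()
    T_o, P_o, W_o, r2x_o = [], [], [], []
    for _ in range(n_orthogonal):
        w = Xd.T @ yc
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_orth = p - (w @ p) * w
        norm_orth = np.linalg.norm(w_orth)
        if norm_orth <= 1e-12 * np.linalg.norm(p):
            log.warning("no class-orthogonal variation left; stopping orthogonal extraction")
            break
        w_orth /= norm_orth
        t_orth = Xd @ w_orth
        p_orth = Xd.T @ t_orth / (t_orth @ t_orth)
        Xd = Xd - np.outer(t_orth, p_orth)
        T_o.append(t_orth)
        P_o.append(p_orth)
        W_o.append(w_orth)
        r2x_o.append((t_orth @ t_orth) * (p_orth @ p_orth) / ssx0)

    w_pred = Xd.T @ yc
    w_pred /= np.linalg.norm(w_pred)
    t_pred = Xd @ w_pred
    tt = t_pred @ t_pred
    p_pred = Xd.T @ t_pred / tt
    c_pred = float(yc @ t_pred / tt)
    r2y = float(1.0 - np.sum((yc - t_pred * c_pred) ** 2) / np.sum(yc**2))
    r2x_pred = float(tt * (p_pred @ p_pred) / ssx0)

    sx = Xs.std(axis=0, ddof=1)
    sy = yc.std(ddof=1)
    cov = Xs.T @ yc / (len(yc) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(sx > 0, cov / (sx * sy), 0.0)

    j = len(T_o)
    return OplsModel(
        t_pred=t_pred,
        p_pred=p_pred,
        w_pred=w_pred,
        c_pred=c_pred,
        T_ortho=np.column_stack(T_o) if j else np.empty((X.shape[0], 0)),
        P_ortho=np.column_stack(P_o) if j else np.empty((X.shape[1], 0)),
        W_ortho=np.column_stack(W_o) if j else np.empty((X.shape[1], 0)),
        r2x_pred=r2x_pred,
        r2x_ortho=np.array(r2x_o),
        r2y=r2y,
        covariance=cov,
        correlation=corr,
        x_scaling=params,
        y_mean=y_mean,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# correlation loadings

def correlation_loadings(
    X: np.ndarray,
    labels: np.ndarray,
    noise_regions: list[tuple[float, float]] | None = None,
    bin_centers: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variable covariance and Pearson correlation with the binary class
    coding, with declared noise regions zeroed.

    Columns: ``bin_center`` (if provided), ``covariance``, ``r``, ``zeroed``
    (inside a noise region), ``degenerate`` (constant column, r set to 0).
    """
    X = np.asarray(X, dtype=float)
    Y, _ = encode_labels(labels)
    if Y.shape[1] != 1:
        raise ValueError("correlation loadings need a binary class vector")
    yc = Y[:, 0] - Y[:, 0].mean()
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    cov = Xc.T @ yc / (n - 1)
    sx = X.std(axis=0, ddof=1)
    sy = yc.std(ddof=1)
    degenerate = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(degenerate, 0.0, cov / (sx * sy))

    zeroed = np.zeros(X.shape[1], dtype=bool)
    if noise_regions:
        if bin_centers is None:
            raise ValueError("noise_regions require bin_centers")
        bin_centers = np.asarray(bin_centers, dtype=float)
        for lo, hi in noise_regions:
            zeroed |= (bin_centers >= lo) & (bin_centers <= hi)
        cov = np.where(zeroed, 0.0, cov)
        r = np.where(zeroed, 0.0, r)

    out = pd.DataFrame({"covariance": cov, "r": r, "zeroed": zeroed, "degenerate": degenerate})
    if bin_centers is not None:
        out.insert(0, "bin_center", np.asarray(bin_centers, dtype=float))
    return out


# ---------------------------------------------------------------------------
# helpers

def nipals_pca(X: np.ndarray, n_components: int, tol: float = NIPALS_TOL) -> tuple[np.ndarray, np.ndarray]:
    """NIPALS in PCA mode (Y = X): returns (scores, loadings).

    Used for cross-checking the iteration against spectral decomposition;
    loadings have unit norm.
    """
    Xd = np.asarray(X, dtype=float) - np.asarray(X, dtype=float).mean(axis=0)
    n, p = Xd.shape
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    for k in range(n_components):
        t = Xd[:, int(np.argmax(Xd.var(axis=0)))].copy()
        for _ in range(NIPALS_MAX_ITER):
            p_vec = Xd.T @ t / (t @ t)
            p_vec /= np.linalg.norm(p_vec)
            t_new = Xd @ p_vec
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        else:
            raise RuntimeError(f"NIPALS PCA did not converge for component {k + 1}")
        Xd = Xd - np.outer(t, p_vec)
        T[:, k] = t
        P[:, k] = p_vec
    return T, P


def suggest_components(
    X: np.ndarray,
    labels: np.ndarray,
    max_components: int = 5,
    min_q2_gain: float = 0.05,
    n_folds: int = 8,
    scaling: str = "center",
    seed: int = 0,
) -> int:
    """Smallest k after which adding a component improves Q2 by less than
    ``min_q2_gain`` (a SIMCA-like stopping convention)."""
    best_k = 1
    prev = cross_validated_q2(X, labels, 1, n_folds, scaling, seed).q2
    for k in range(2, max_components + 1):
        q2 = cross_validated_q2(X, labels, k, n_folds, scaling, seed).q2
        if q2 - prev < min_q2_gain:
            break
        prev = q2
        best_k = k
    return best_k
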