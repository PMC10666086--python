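"""NIPALS partial least squares with discriminant-analysis and regression
front ends, plus leave-one-out cross-validation.

PLS extracts latent variables (LVs) — pairs of a spectral weight vector and
per-sample scores — that maximise the covariance between the spectral
matrix X and the response Y (one-hot class membership for PLS-DA, a
concentration column for PLS-R).  The implementation is the classic NIPALS
algorithm with X- and Y-deflation.  Mean-centering is optional and off by
default: with raw (uncentered) operation there is no intercept and the
coefficient matrix B alone reconstructs yhat = X B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls",
    "plsda_fit",
    "plsda_predict",
    "loo_crossval",
    "rmse_curve",
    "one_hot",
]


@dataclass
class PLSModel:
    W: np.ndarray  # x-weights, pixels x n_lv
    P: np.ndarray  # x-loadings, pixels x n_lv
    Q: np.ndarray  # y-loadings, n_targets x n_lv
    T: np.ndarray  # x-scores, samples x n_lv
    B: np.ndarray  # regression coefficients, pixels x n_targets
    n_lv: int
    centered: bool
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None
    class_names: list = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous response yhat for new rows X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.B.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns; model expects {self.B.shape[0]}"
            )
        if self.centered:
            return (X - self.x_mean) @ self.B + self.y_mean
        return X @ self.B

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new rows onto the latent-variable scores."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.centered:
            X = X - self.x_mean
        # scores via the rotation R = W (P^T W)^-1
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return X @ R


@dataclass
class CVResult:
    class_names: list
    confusion: np.ndarray  # rows = truth, cols = prediction
    per_sample_prediction: list
    per_sample_yhat: np.ndarray

    @property
    def per_class_recall(self) -> dict:
        totals = self.confusion.sum(axis=1)
        return {
            c: (self.confusion[i, i] / totals[i] if totals[i] else np.nan)
            for i, c in enumerate(self.class_names)
        }

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def _sign_fix(w: np.ndarray) -> float:
    """Sign convention: the first element that is nonzero (relative to the
    vector's scale) is made positive, so LVs are comparable across runs."""
    thresh = 1e-12 * np.max(np.abs(w))
    nz = np.nonzero(np.abs(w) > thresh)[0]
    if nz.size == 0:
        return 1.0
    return 1.0 if w[nz[0]] > 0 else -1.0


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_lv: int,
    centered: bool = False,
    class_names: list | None = None,
    tol: float = 1e-13,
    max_iter: int = 2000,
) -> PLSModel:
    """Fit a PLS model by NIPALS.

    Per latent variable: iterate w ~ X^T u, t = X w, q ~ Y^T t, u = Y q to
    convergence, then deflate X (and Y) by the rank-one outer products.
    Extraction stops early if X deflates to (numerical) zero before ``n_lv``
    components; the achieved count is recorded in ``n_lv``.
    """
    X = np.asarray(X, dtype=float).copy()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = Y.copy()
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    n, p = X.shape
    if n_lv > min(n, p):
        raise ValueError(f"n_lv={n_lv} exceeds min(samples, pixels)={min(n, p)}")
    x_norm0 = np.linalg.norm(X)
    if x_norm0 == 0:
        raise ValueError("X has zero variance; nothing to fit")
    x_mean = X.mean(axis=0) if centered else None
    y_mean = Y.mean(axis=0) if centered else None
    if centered:
        X -= x_mean
        Y -= y_mean
        if np.linalg.norm(X) < 1e-12 * x_norm0:
            raise ValueError("X has zero variance after centering")
        x_norm0 = np.linalg.norm(X)

    Ws, Ps, Qs, Ts = [], [], [], []
    for _ in range(n_lv):
        if np.linalg.norm(X) < 1e-12 * x_norm0 or np.linalg.norm(Y) < 1e-14:
            break  # rank exhausted or response fully explained
        u = Y[:, np.argmax((Y**2).sum(axis=0))].copy()
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t = X @ w
            tt = t @ t
            if tt == 0:
                break
            q = Y.T @ t / tt
            nq = q @ q
            if nq == 0:
                break
            u = Y @ q / nq
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        if nw == 0 or tt == 0:
            break
        s = _sign_fix(w)
        w, t, q = s * w, s * t, s * q
        p_load = X.T @ t / tt
        X -= np.outer(t, p_load)
        Y -= np.outer(t, q)
        Ws.append(w)
        Ps.append(p_load)
        Qs.append(q)
        Ts.append(t)

    if not Ws:
        raise ValueError("no latent variable could be extracted")
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    Q = np.column_stack(Qs)
    T = np.column_stack(Ts)
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSModel(
        W=W, P=P, Q=Q, T=T, B=B, n_lv=W.shape[1], centered=centered,
        x_mean=x_mean, y_mean=y_mean, class_names=list(class_names or []),
    )


def one_hot(labels: list, class_names: list | None = None) -> tuple[np.ndarray, list]:
    """One-hot response matrix; class order is sorted unique labels unless
    given explicitly."""
    if class_names is None:
        class_names = sorted(set(labels))
    idx = {c: i for i, c in enumerate(class_names)}
    Y = np.zeros((len(labels), len(class_names)))
    for r, lab in enumerate(labels):
        if lab not in idx:
            raise ValueError(f"label {lab!r} not in class_names")
        Y[r, idx[lab]] = 1.0
    return Y, list(class_names)


def plsda_fit(
    X: np.ndarray, labels: list, n_lv: int, centered: bool = False,
    class_names: list | None = None,
) -> PLSModel:
    """PLS-DA: PLS on one-hot class membership."""
    Y, names = one_hot(labels, class_names)
    return fit_pls(X, Y, n_lv, centered=centered, class_names=names)


def plsda_predict(model: PLSModel, X: np.ndarray) -> tuple[list, np.ndarray]:
    """Class prediction by argmax over the continuous class responses.

    Ties resolve to the earliest class in ``class_names`` order (numpy argmax
    already returns the first maximal index).
    """
    if not model.class_names:
        raise ValueError("model has no class names; was it fitted for regression?")
    yhat = model.predict(X)
    labels = [model.class_names[int(i)] for i in np.argmax(yhat, axis=1)]
    return labels, yhat


def loo_crossval(
    X: np.ndarray, labels: list, n_lv: int, centered: bool = False
) -> CVResult:
    """Leave-one-out cross-validation of the PLS-DA classifier.

    Each sample in turn is removed, the model refitted from scratch on the
    remaining rows (including any centering), and the held-out sample
    predicted.  Fully deterministic: there is no randomness in the model.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    class_names = sorted(set(labels))
    counts = {c: labels.count(c) for c in class_names}
    singletons = [c for c, n in counts.items() if n < 2]
    if singletons:
        raise ValueError(f"classes with fewer than two samples: {singletons}")
    n = X.shape[0]
    preds: list = []
    yhats = np.zeros((n, len(class_names)))
    for i in range(n):
        keep = np.arange(n) != i
        model = plsda_fit(X[keep], [l for j, l in enumerate(labels) if j != i],
                          n_lv, centered=centered, class_names=class_names)
        lab, yh = plsda_predict(model, X[i])
        preds.append(lab[0])
        yhats[i] = yh[0]
    idx = {c: k for k, c in enumerate(class_names)}
    confusion = np.zeros((len(class_names), len(class_names)), dtype=int)
    for truth, pred in zip(labels, preds):
        confusion[idx[truth], idx[pred]] += 1
    return CVResult(
        class_names=class_names,
        confusion=confusion,
        per_sample_prediction=preds,
        per_sample_yhat=yhats,
    )


def rmse_curve(
    X: np.ndarray, labels: list, max_lv: int, centered: bool = False
) -> np.ndarray:
    """Leave-one-out RMSE of the continuous class response against the
    one-hot truth, for every LV count from 1 to ``max_lv``.  The curve is
    returned as-is; the working LV count is a configuration choice, not an
    automatic elbow pick."""
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    Y, names = one_hot(list(labels))
    out = np.empty(max_lv)
    for k in range(1, max_lv + 1):
        cv = loo_crossval(X, labels, k, centered=centered)
        out[k - 1] = float(np.sqrt(np.mean((cv.per_sample_yhat - Y) ** 2)))
    return out
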