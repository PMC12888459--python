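"""From-scratch NIPALS latent-variable models: PLS1, OPLS, OPLS-DA, PCA.

OPLS (orthogonal projections to latent structures) splits predictor variation
into a part correlated with the single response y and parts orthogonal to it.
The predictive weight vector ``w ∝ X'y`` is fixed once; each orthogonal
component removes from X the direction of the current loading that is
orthogonal to ``w`` (Trygg–Wold), and the final predictive component is
fitted on the filtered X.  With zero orthogonal components the model is
exactly a one-component PLS1.

Also provided: VIP (variable importance in projection, mean square one by
construction), k-fold cross-validated Q², a label-permutation test for model
validity, and a NIPALS PCA for unsupervised overview.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import ValidationError

__all__ = ["OPLSModel", "PermutationReport", "PCAResult", "fit_pls1",
           "fit_opls", "vip", "cross_validate_q2", "permutation_test",
           "fit_oplsda", "pca"]

_EPS = 1e-12


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (observations × variables)")
    return X, [f"x{j}" for j in range(X.shape[1])]


def _as_vector(y) -> np.ndarray:
    v = np.asarray(y, dtype=float).ravel()
    return v


@dataclass
class OPLSModel:
    """Fitted PLS1/OPLS model with diagnostics.

    Predictive parts are stored column-wise (``w``, ``t``, ``p_load``, ``q``
    with one column/entry per predictive component; OPLS always has exactly
    one), orthogonal parts likewise in ``w_orth``/``t_orth``/``p_orth``.
    """

    kind: str                      # "pls1" | "opls"
    w: np.ndarray                  # variables × n_pred
    t: np.ndarray                  # observations × n_pred
    p_load: np.ndarray             # variables × n_pred
    q: np.ndarray                  # n_pred
    w_orth: np.ndarray             # variables × n_orth
    t_orth: np.ndarray             # observations × n_orth
    p_orth: np.ndarray             # variables × n_orth
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    r2x: float
    r2x_per_component: np.ndarray
    r2y: float
    feature_names: list[str]
    y_train: np.ndarray
    q2: float | None = None
    classes_: tuple | None = None  # set by fit_oplsda (binary)

    @property
    def n_pred(self) -> int:
        return self.w.shape[1]

    @property
    def n_orth(self) -> int:
        return self.w_orth.shape[1]

    def _prepare(self, X) -> np.ndarray:
        xm, _ = _as_matrix(X)
        return (xm - self.x_mean) / self.x_scale

    def predict(self, X) -> np.ndarray:
        """Predict y for new observations (orthogonal variation removed first)."""
        xc = self._prepare(X)
        for a in range(self.n_orth):
            t_o = xc @ self.w_orth[:, a]
            xc = xc - np.outer(t_o, self.p_orth[:, a])
        if self.n_pred == 1:
            t_new = xc @ self.w[:, 0]
            return self.y_mean + t_new * self.q[0]
        b = self.w @ np.linalg.solve(self.p_load.T @ self.w, self.q)
        return self.y_mean + xc @ b

    def fitted(self) -> np.ndarray:
        """Training-set predictions, mean + Σ t_a q_a."""
        return self.y_mean + self.t @ self.q

    def scores(self) -> pd.DataFrame:
        """Predictive and orthogonal score vectors for plotting."""
        cols = {f"t{a + 1}": self.t[:, a] for a in range(self.n_pred)}
        cols.update({f"to{a + 1}": self.t_orth[:, a] for a in range(self.n_orth)})
        return pd.DataFrame(cols)


def _center_scale(X, y, scale):
    xm, names = _as_matrix(X)
    yv = _as_vector(y)
    if xm.shape[0] != yv.size:
        raise ValidationError("X and y disagree on observation count")
    if xm.shape[0] < 2:
        raise ValidationError("need at least 2 observations")
    if np.std(yv) == 0:
        raise ValidationError("zero-variance response")
    x_mean = xm.mean(axis=0)
    if scale:
        sd = xm.std(axis=0, ddof=1)
        x_scale = np.where(sd < _EPS, 1.0, sd)
    else:
        x_scale = np.ones(xm.shape[1])
    xc = (xm - x_mean) / x_scale
    y_mean = float(yv.mean())
    yc = yv - y_mean
    return xc, yc, x_mean, x_scale, y_mean, names, yv


def fit_pls1(X, y, n_comp: int = 1, scale: bool = True) -> OPLSModel:
    """NIPALS PLS1 regression with ``n_comp`` components.

    Per component: ``w = X'y/‖X'y‖``, ``t = Xw``, ``p = X't/(t't)``,
    ``q = y't/(t't)``, then X is deflated by ``t p'``.  When the residual
    covariance ``X'y`` vanishes before ``n_comp`` components the loop stops
    early with a warning.
    """
    xc, yc, x_mean, x_scale, y_mean, names, yv = _center_scale(X, y, scale)
    rank = np.linalg.matrix_rank(xc)
    if n_comp < 1:
        raise ValidationError("n_comp must be >= 1")
    if n_comp > rank:
        raise ValidationError(f"n_comp={n_comp} exceeds rank(X)={rank}")

    ss_x0 = (xc ** 2).sum()
    n, p = xc.shape
    W = np.zeros((p, n_comp))
    T = np.zeros((n, n_comp))
    P = np.zeros((p, n_comp))
    Q = np.zeros(n_comp)
    r2x_comp = np.zeros(n_comp)
    xd = xc.copy()
    yd = yc.copy()
    used = 0
    for a in range(n_comp):
        cov = xd.T @ yd
        norm = np.linalg.norm(cov)
        if norm < _EPS:
            warnings.warn(f"response variance exhausted after {a} components",
                          stacklevel=2)
            break
        w = cov / norm
        t = xd @ w
        tt = float(t @ t)
        pl = xd.T @ t / tt
        qa = float(yd @ t / tt)
        xd = xd - np.outer(t, pl)
        yd = yd - qa * t
        W[:, a], T[:, a], P[:, a], Q[a] = w, t, pl, qa
        r2x_comp[a] = tt * float(pl @ pl) / ss_x0 if ss_x0 > 0 else 0.0
        used += 1
    W, T, P, Q, r2x_comp = W[:, :used], T[:, :used], P[:, :used], Q[:used], r2x_comp[:used]

    fitted = y_mean + T @ Q
    ss_res = float(((yv - fitted) ** 2).sum())
    ss_tot = float((yc ** 2).sum())
    r2y = 1.0 - ss_res / ss_tot
    empty = np.zeros((p, 0))
    return OPLSModel(kind="pls1", w=W, t=T, p_load=P, q=Q,
                     w_orth=empty, t_orth=np.zeros((n, 0)), p_orth=empty,
                     x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
                     r2x=float(r2x_comp.sum()), r2x_per_component=r2x_comp,
                     r2y=r2y, feature_names=names, y_train=yv)


def fit_opls(X, y, n_orth: int = 1, scale: bool = True) -> OPLSModel:
    """OPLS with one predictive and ``n_orth`` orthogonal components.

    The predictive weight ``w`` is computed once from the original X; each
    round removes the orthogonal direction ``w_o ∝ p − (w'p)w`` from X.  When
    no orthogonal variation remains (``‖w_o‖ ≈ 0``) the loop stops early with
    a warning.  With ``n_orth=0`` predictions coincide with one-component
    PLS1.
    """
    if n_orth < 0:
        raise ValidationError("n_orth must be >= 0")
    xc, yc, x_mean, x_scale, y_mean, names, yv = _center_scale(X, y, scale)
    n, p = xc.shape
    ss_x0 = (xc ** 2).sum()

    cov = xc.T @ yc
    norm = np.linalg.norm(cov)
    if norm < _EPS:
        raise ValidationError("X carries no covariance with y")
    w = cov / norm

    Wo = np.zeros((p, n_orth))
    To = np.zeros((n, n_orth))
    Po = np.zeros((p, n_orth))
    r2x_orth = np.zeros(n_orth)
    xd = xc.copy()
    used = 0
    for a in range(n_orth):
        t = xd @ w
        tt = float(t @ t)
        pl = xd.T @ t / tt
        w_o = pl - float(w @ pl) * w
        nw = np.linalg.norm(w_o)
        if nw < _EPS:
            warnings.warn(f"no orthogonal variation left after {a} components",
                          stacklevel=2)
            break
        w_o = w_o / nw
        t_o = xd @ w_o
        tto = float(t_o @ t_o)
        p_o = xd.T @ t_o / tto
        xd = xd - np.outer(t_o, p_o)
        Wo[:, a], To[:, a], Po[:, a] = w_o, t_o, p_o
        r2x_orth[a] = tto * float(p_o @ p_o) / ss_x0 if ss_x0 > 0 else 0.0
        used += 1
    Wo, To, Po, r2x_orth = Wo[:, :used], To[:, :used], Po[:, :used], r2x_orth[:used]

    t = xd @ w
    tt = float(t @ t)
    pl = xd.T @ t / tt
    q = float(yc @ t / tt)
    r2x_pred = tt * float(pl @ pl) / ss_x0 if ss_x0 > 0 else 0.0

    fitted = y_mean + t * q
    ss_res = float(((yv - fitted) ** 2).sum())
    ss_tot = float((yc ** 2).sum())
    r2y = 1.0 - ss_res / ss_tot
    r2x_comp = np.concatenate([[r2x_pred], r2x_orth])
    return OPLSModel(kind="opls", w=w[:, None], t=t[:, None], p_load=pl[:, None],
                     q=np.array([q]), w_orth=Wo, t_orth=To, p_orth=Po,
                     x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
                     r2x=float(r2x_comp.sum()), r2x_per_component=r2x_comp,
                     r2y=r2y, feature_names=names, y_train=yv)


def vip(model: OPLSModel, mode: str = "predictive") -> pd.Series:
    """Variable importance in projection, mean square one across variables.

    ``predictive`` (default) sums y-predictive components only, weighting by
    the y-variance each explains (``SSY_a = q_a²·t_a't_a``).  ``total``
    additionally includes orthogonal components weighted by the X-variation
    they explain, after Galindo-Prieto's total VIP for OPLS.
    """
    if model.w.size == 0:
        raise ValidationError("model has no fitted components")
    p = len(model.feature_names)
    ssy = model.q ** 2 * np.einsum("ij,ij->j", model.t, model.t)
    num = np.zeros(p)
    denom = 0.0
    for a in range(model.n_pred):
        wa = model.w[:, a]
        num += ssy[a] * (wa / np.linalg.norm(wa)) ** 2
        denom += ssy[a]
    if mode == "total":
        ssx0 = None
        for a in range(model.n_orth):
            wo = model.w_orth[:, a]
            ssx_o = float(model.t_orth[:, a] @ model.t_orth[:, a]) * float(
                model.p_orth[:, a] @ model.p_orth[:, a])
            num += ssx_o * (wo / np.linalg.norm(wo)) ** 2
            denom += ssx_o
    elif mode != "predictive":
        raise ValueError(f"unknown VIP mode {mode!r}")
    v = np.sqrt(p * num / denom)
    return pd.Series(v, index=model.feature_names, name="vip")


def _fold_assignment(n: int, folds: int, seed: int | None) -> np.ndarray:
    order = np.arange(n)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(n)
    assign = np.empty(n, dtype=int)
    assign[order] = np.arange(n) % folds
    return assign


def cross_validate_q2(X, y, folds: int = 7, seed: int | None = None,
                      n_orth: int = 1, scale: bool = True,
                      method: str = "opls", n_comp: int = 1) -> float:
    """K-fold cross-validated Q² = 1 − PRESS/SS_tot.

    Fold assignment is round-robin on observation order ("venetian blinds");
    passing a seed shuffles the assignment instead.  ``folds`` above the
    number of observations degrades to leave-one-out with a warning.
    """
    xm, _ = _as_matrix(X)
    yv = _as_vector(y)
    n = yv.size
    if n < 3:
        raise ValidationError("cross-validation needs at least 3 observations")
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if folds > n:
        warnings.warn(f"folds={folds} > n={n}; using leave-one-out", stacklevel=2)
        folds = n
    assign = _fold_assignment(n, folds, seed)
    press = 0.0
    for f in range(folds):
        test = assign == f
        train = ~test
        if method == "opls":
            m = fit_opls(xm[train], yv[train], n_orth=n_orth, scale=scale)
        elif method == "pls1":
            m = fit_pls1(xm[train], yv[train], n_comp=n_comp, scale=scale)
        else:
            raise ValueError(f"unknown method {method!r}")
        pred = m.predict(xm[test])
        press += float(((yv[test] - pred) ** 2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    return 1.0 - press / ss_tot


@dataclass
class PermutationReport:
    """Response-permutation null distribution for R²Y and Q²."""

    n_perm: int
    seed: int
    r2y: float
    q2: float
    r2y_perm: np.ndarray
    q2_perm: np.ndarray

    @property
    def n_exceed(self) -> int:
        """Permutations whose Q² reaches or beats the original."""
        return int((self.q2_perm >= self.q2).sum())

    def quantiles(self, qs=(0.5, 0.95, 0.99)) -> pd.DataFrame:
        return pd.DataFrame(
            {"r2y": np.quantile(self.r2y_perm, qs),
             "q2": np.quantile(self.q2_perm, qs)},
            index=[f"q{q:g}" for q in qs],
        )


def permutation_test(X, y, n_perm: int = 200, seed: int = 0,
                     n_orth: int = 1, folds: int = 7,
                     scale: bool = True) -> PermutationReport:
    """Refit the OPLS model under random permutations of y.

    A valid model shows the original Q² well above the permuted distribution;
    ``n_exceed`` counts permutations reaching it.  Deterministic for a fixed
    seed.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    xm, _ = _as_matrix(X)
    yv = _as_vector(y)
    model = fit_opls(xm, yv, n_orth=n_orth, scale=scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q2 = cross_validate_q2(xm, yv, folds=folds, n_orth=n_orth, scale=scale)
    rng = np.random.default_rng(seed)
    r2y_perm = np.empty(n_perm)
    q2_perm = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(yv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mp = fit_opls(xm, yp, n_orth=n_orth, scale=scale)
            r2y_perm[i] = mp.r2y
            q2_perm[i] = cross_validate_q2(xm, yp, folds=folds, n_orth=n_orth,
                                           scale=scale)
    return PermutationReport(n_perm=n_perm, seed=seed, r2y=model.r2y, q2=q2,
                             r2y_perm=r2y_perm, q2_perm=q2_perm)


def fit_oplsda(X, labels, n_orth: int = 1, scale: bool = True):
    """OPLS discriminant analysis.

    Binary labels map to a ±1 dummy response and a single OPLS model is
    returned (class order recorded in ``classes_``); with more classes a
    one-vs-all model per class is returned as a dict.
    """
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist(), key=str)
    if len(classes) < 2:
        raise ValidationError("OPLS-DA needs at least 2 classes")
    if len(classes) == 2:
        y = np.where(labels == classes[1], 1.0, -1.0)
        model = fit_opls(X, y, n_orth=n_orth, scale=scale)
        model.classes_ = (classes[0], classes[1])
        return model
    models = {}
    for c in classes:
        y = np.where(labels == c, 1.0, -1.0)
        m = fit_opls(X, y, n_orth=n_orth, scale=scale)
        m.classes_ = ("rest", c)
        models[c] = m
    return models


@dataclass
class PCAResult:
    scores: np.ndarray     # observations × n_comp
    loadings: np.ndarray   # variables × n_comp
    r2x: np.ndarray        # explained fraction per component
    x_mean: np.ndarray
    x_scale: np.ndarray


def pca(X, n_comp: int = 2, scale: bool = False, tol: float = 1e-10,
        max_iter: int = 1000) -> PCAResult:
    """Column-centered NIPALS PCA (unit-variance scaling optional)."""
    xm, _ = _as_matrix(X)
    n, p = xm.shape
    if n_comp > min(n - 1, p):
        raise ValidationError(f"n_comp={n_comp} exceeds min(n-1, p)={min(n - 1, p)}")
    x_mean = xm.mean(axis=0)
    if scale:
        sd = xm.std(axis=0, ddof=1)
        x_scale = np.where(sd < _EPS, 1.0, sd)
    else:
        x_scale = np.ones(p)
    xd = (xm - x_mean) / x_scale
    ss0 = (xd ** 2).sum()
    T = np.zeros((n, n_comp))
    P = np.zeros((p, n_comp))
    r2x = np.zeros(n_comp)
    for a in range(n_comp):
        j = int(np.argmax((xd ** 2).sum(axis=0)))
        t = xd[:, j].copy()
        if float(t @ t) < _EPS:
            T, P, r2x = T[:, :a], P[:, :a], r2x[:a]
            break
        for _ in range(max_iter):
            pl = xd.T @ t / float(t @ t)
            pl /= np.linalg.norm(pl)
            t_new = xd @ pl
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t)):
                t = t_new
                break
            t = t_new
        pl = xd.T @ t / float(t @ t)
        pl /= np.linalg.norm(pl)
        t = xd @ pl
        xd = xd - np.outer(t, pl)
        T[:, a], P[:, a] = t, pl
        r2x[a] = float(t @ t) / ss0 if ss0 > 0 else 0.0
    return PCAResult(scores=T, loadings=P, r2x=r2x, x_mean=x_mean,
                     x_scale=x_scale)
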