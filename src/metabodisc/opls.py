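"""OPLS-DA from scratch: Pareto scaling, O-PLS NIPALS, sevenfold CV, CV-ANOVA.

Orthogonal projections to latent structures discriminant analysis separates
class-predictive variation from class-orthogonal variation before a single
predictive component regresses on class membership. For two classes, y is
coded +/-1 (the group listed second in the metadata codes +1, so positive
coefficients read as "increased in the resistant-analogue group") and
centred.

Per orthogonal round on the current X:

    w      = X'y / (y'y), normalised to unit length
    t      = X w
    p      = X't / (t't)
    w_orth = p - (w'p) w, normalised
    t_orth = X w_orth
    p_orth = X't_orth / (t_orth't_orth)
    X     <- X - t_orth p_orth'

After the requested orthogonal rounds the predictive component
(w, t_pred, p_pred, c) is fitted on the deflated X. Model quality is
summarised by R2X (fraction of scaled-X variance captured, split into
predictive and orthogonal parts), R2Y, and cross-validated Q2 = 1 -
PRESS/SSY from stratified sevenfold cross-validation in which scaling and
the model are refit on the training rows of every fold. CV-ANOVA turns
(SSY - PRESS) vs PRESS into an F test of model significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ScaledMatrix",
    "OplsModel",
    "CvResult",
    "CvAnovaResult",
    "pareto_scale",
    "encode_labels",
    "fit_oplsda",
    "predict",
    "cross_validate",
    "cv_anova",
    "permutation_q2",
]

_EPS = 1e-12


@dataclass
class ScaledMatrix:
    """Column-scaled data plus the statistics needed to undo or reapply it."""

    values: np.ndarray
    column_means: np.ndarray
    column_scales: np.ndarray
    scaling_mode: str  # center | unit-variance | pareto
    constant_mask: np.ndarray  # True where the column had zero variance

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Apply this scaler (fit on training data) to new rows."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != self.values.shape[1]:
            raise ValueError(
                f"variable count mismatch: {X_new.shape[1]} vs {self.values.shape[1]}"
            )
        return (X_new - self.column_means) / self.column_scales

    def unscale(self, values: np.ndarray) -> np.ndarray:
        return values * self.column_scales + self.column_means


def pareto_scale(X: np.ndarray, mode: str = "pareto") -> ScaledMatrix:
    """Centre each column and divide by a mode-dependent scale.

    pareto: sqrt of the sample s.d. (ddof=1) — intermediate between
    mean-centring and unit-variance scaling, preserving some intensity
    weighting of NMR bins. Zero-variance columns are centred only (scale
    recorded as 1) and flagged constant.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("scaling requires a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = sds <= _EPS * np.maximum(1.0, np.abs(means))
    if mode == "pareto":
        scales = np.sqrt(sds)
    elif mode == "unit-variance":
        scales = sds.copy()
    elif mode == "center":
        scales = np.ones_like(sds)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    scales[constant] = 1.0
    return ScaledMatrix(
        values=(X - means) / scales,
        column_means=means,
        column_scales=scales,
        scaling_mode=mode,
        constant_mask=constant,
    )


def encode_labels(labels: list[str]) -> tuple[np.ndarray, dict[str, int]]:
    """Code a two-class label list as -1/+1; the group appearing second codes +1."""
    order = list(dict.fromkeys(labels))
    if len(order) != 2:
        raise ValueError(f"need exactly two classes, got {order}")
    coding = {order[0]: -1, order[1]: +1}
    return np.array([coding[l] for l in labels], dtype=float), coding


@dataclass
class OplsModel:
    w: np.ndarray  # predictive weight, unit norm
    t_pred: np.ndarray
    p_pred: np.ndarray
    c: float  # regression scalar y ~ t_pred
    w_orth: np.ndarray  # (k, p)
    t_orth: np.ndarray  # (n, k)
    p_orth: np.ndarray  # (k, p)
    y_mean: float
    R2X: float
    R2X_pred: float
    R2X_orth: float
    R2Y: float
    class_coding: dict[str, int] | None = None

    @property
    def n_orth(self) -> int:
        return self.w_orth.shape[0]


def _weight(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    w = X.T @ y / (y @ y)
    nrm = np.linalg.norm(w)
    if nrm <= _EPS:
        raise ValueError("degenerate weight vector: X carries no covariance with y")
    return w / nrm


def fit_oplsda(
    X_scaled: np.ndarray,
    y_coded: np.ndarray,
    n_orth: int = 1,
    class_coding: dict[str, int] | None = None,
) -> OplsModel:
    """Fit an OPLS model with one predictive and ``n_orth`` orthogonal components.

    ``X_scaled`` must already be column-scaled/centred; ``y_coded`` is the
    +/-1 class coding (centred internally). With ``n_orth=0`` the model is
    exactly single-component PLS1.
    """
    X = np.asarray(X_scaled, dtype=float)
    y = np.asarray(y_coded, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) and y length n")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    y_mean = y.mean()
    y = y - y_mean
    if y @ y <= _EPS:
        raise ValueError("single-class y: cannot fit a discriminant model")

    ssx = float((X**2).sum())
    if ssx <= _EPS:
        raise ValueError("X has no variance after scaling")

    Xd = X.copy()
    w_orth_list, t_orth_list, p_orth_list = [], [], []
    for k in range(n_orth):
        w = _weight(Xd, y)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        wo = p - (w @ p) * w
        nrm = np.linalg.norm(wo)
        if nrm <= _EPS:
            raise ValueError(f"degenerate orthogonal component {k + 1}: zero weight")
        wo /= nrm
        to = Xd @ wo
        to_ss = to @ to
        if to_ss <= _EPS:
            raise ValueError(f"degenerate orthogonal component {k + 1}: zero score")
        po = Xd.T @ to / to_ss
        Xd = Xd - np.outer(to, po)
        w_orth_list.append(wo)
        t_orth_list.append(to)
        p_orth_list.append(po)

    w = _weight(Xd, y)
    t = Xd @ w
    t_ss = t @ t
    if t_ss <= _EPS:
        raise ValueError("degenerate predictive component: zero score norm")
    p = Xd.T @ t / t_ss
    c = float(t @ y / t_ss)

    resid = Xd - np.outer(t, p)
    ss_orth = sum(float(to @ to) * float(po @ po)
                  for to, po in zip(t_orth_list, p_orth_list))
    r2x_pred = t_ss * float(p @ p) / ssx
    r2x_orth = ss_orth / ssx
    r2x = 1.0 - float((resid**2).sum()) / ssx
    r2y = 1.0 - float(((y - t * c) ** 2).sum()) / float(y @ y)

    k = len(w_orth_list)
    pcols = X.shape[1]
    return OplsModel(
        w=w,
        t_pred=t,
        p_pred=p,
        c=c,
        w_orth=np.array(w_orth_list).reshape(k, pcols),
        t_orth=np.array(t_orth_list).T.reshape(X.shape[0], k),
        p_orth=np.array(p_orth_list).reshape(k, pcols),
        y_mean=y_mean,
        R2X=r2x,
        R2X_pred=r2x_pred,
        R2X_orth=r2x_orth,
        R2Y=r2y,
        class_coding=class_coding,
    )


def predict(model: OplsModel, X_new_scaled: np.ndarray) -> np.ndarray:
    """Predict class scores for new rows scaled with the training scaler.

    Orthogonal variation is stripped with the training w_orth/p_orth sequence,
    then y_hat = t_new * c (+ the training y mean, returning to the +/-1 scale).
    """
    X = np.asarray(X_new_scaled, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"variable count mismatch: {X.shape[1]} vs {model.w.shape[0]}"
        )
    Xf = X.copy()
    for wo, po in zip(model.w_orth, model.p_orth):
        to = Xf @ wo
        Xf = Xf - np.outer(to, po)
    t_new = Xf @ model.w
    return t_new * model.c + model.y_mean


@dataclass
class CvResult:
    fold_map: np.ndarray  # sample -> fold index
    oof_predictions: np.ndarray
    PRESS: float
    SSY: float
    Q2: float
    n_folds: int
    n_components: int  # predictive + orthogonal


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Round-robin fold assignment within each class, in seeded shuffled order."""
    fold_map = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_map[idx] = np.arange(len(idx)) % n_folds
    return fold_map


def cross_validate(
    X: np.ndarray,
    y_coded: np.ndarray,
    n_orth: int = 1,
    n_folds: int = 7,
    seed: int = 0,
    scaling_mode: str = "pareto",
    global_scaling: bool = False,
) -> CvResult:
    """Stratified k-fold cross-validation of the OPLS model.

    By default the scaler is refit on the training rows of every fold
    (leakage-free). ``global_scaling=True`` instead scales the full matrix
    once, mimicking chemometrics packages that cross-validate after a single
    global scaling pass.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_coded, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    fold_map = _stratified_folds(y, n_folds, rng)
    for f in range(n_folds):
        if len(np.unique(y[fold_map != f])) < 2:
            raise ValueError(f"fold {f}: training split lost a whole class")

    scaler_full = pareto_scale(X, mode=scaling_mode) if global_scaling else None
    oof = np.empty(n)
    for f in range(n_folds):
        test = fold_map == f
        train = ~test
        if global_scaling:
            Xtr, Xte = scaler_full.values[train], scaler_full.values[test]
        else:
            scaler = pareto_scale(X[train], mode=scaling_mode)
            Xtr, Xte = scaler.values, scaler.transform(X[test])
        model = fit_oplsda(Xtr, y[train], n_orth=n_orth)
        oof[test] = predict(model, Xte)

    press = float(((y - oof) ** 2).sum())
    ssy = float(((y - y.mean()) ** 2).sum())
    return CvResult(
        fold_map=fold_map,
        oof_predictions=oof,
        PRESS=press,
        SSY=ssy,
        Q2=1.0 - press / ssy,
        n_folds=n_folds,
        n_components=1 + n_orth,
    )


@dataclass
class CvAnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def cv_anova(cv: CvResult) -> CvAnovaResult:
    """F test of cross-validated predictive power.

    F = ((SSY - PRESS)/df1) / (PRESS/df2) with df1 = number of model
    components (predictive + orthogonal) and df2 = n - 1 - df1; p is the
    upper tail of F(df1, df2). PRESS >= SSY clamps F at 0 (p = 1). The dfs
    are recorded so the p-value is auditable.
    """
    n = len(cv.oof_predictions)
    df1 = cv.n_components
    df2 = n - 1 - df1
    if df2 <= 0:
        raise ValueError("not enough samples for CV-ANOVA degrees of freedom")
    if cv.PRESS >= cv.SSY or cv.PRESS <= 0:
        f_stat = 0.0 if cv.PRESS >= cv.SSY else np.inf
    else:
        f_stat = ((cv.SSY - cv.PRESS) / df1) / (cv.PRESS / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return CvAnovaResult(F=float(f_stat), df1=df1, df2=df2, p=p)


def permutation_q2(
    X: np.ndarray,
    y_coded: np.ndarray,
    n_orth: int = 1,
    n_permutations: int = 200,
    n_folds: int = 7,
    seed: int = 0,
    scaling_mode: str = "pareto",
) -> np.ndarray:
    """Q2 under label permutation: the null distribution of model predictability."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y_coded, dtype=float)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        cv = cross_validate(
            X, y_perm, n_orth=n_orth, n_folds=n_folds,
            seed=int(rng.integers(2**31)), scaling_mode=scaling_mode,
        )
        out[i] = cv.Q2
    return out
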