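"""Latent-variable modeling: PCA, PLS-DA, OPLS-DA and their validation.

PLS-DA is fitted by NIPALS on a centered binary response (for a single
response the per-component weight vector has the closed form
w = X'y / ||X'y||). OPLS-DA first removes components of X-variation
orthogonal to the response (orthogonal signal correction), then fits a
single predictive component tp1 carrying the class contrast.

Validation follows chemometrics convention: Q2 = 1 - PRESS/SS from
stratified 7-fold cross-validation, response permutation testing (RPT)
with R2Y/Q2 intercepts and an exchangeability-exact empirical p-value,
and CV-ANOVA, an F-test of the cross-validated residuals against the
total corrected response variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, FitError, FoldError
from .preprocess import BinnedMatrix

DEFAULT_CV_SEED = 1729  # fixed fold seed: Q2 is deterministic for given data


def _as_array(X) -> np.ndarray:
    """Extract the modeling matrix; masked (water) bins are dropped."""
    if isinstance(X, BinnedMatrix):
        return np.asarray(X.active_values, dtype=float)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise FitError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


def encode_labels(y) -> tuple[np.ndarray, tuple[str, str]]:
    """Encode two-class labels as {0, 1}; the second class (alphabetical) is 1."""
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise FitError(f"need exactly two classes, got {classes}")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < 2:
        raise FitError(f"each class needs >= 2 samples, got {dict(zip(classes, counts))}")
    return (y == classes[1]).astype(float), (str(classes[0]), str(classes[1]))


def _scale_fit(X: np.ndarray, scaling: str):
    mean = X.mean(axis=0)
    if scaling == "center":
        scale = np.ones(X.shape[1])
    elif scaling in ("uv", "pareto"):
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        scale = sd if scaling == "uv" else np.sqrt(sd)
    else:
        raise ConfigError(f"unknown scaling {scaling!r}")
    return mean, scale


@dataclass
class LatentModel:
    """Fitted scores/loadings/weights for PCA, PLS-DA or OPLS-DA."""

    kind: str
    scores: np.ndarray  # samples x components (predictive for oplsda)
    loadings: np.ndarray  # variables x components
    weights: np.ndarray | None
    r2x: float
    r2y: float | None
    q2: float | None
    n_components: int
    n_orth: int
    scaling: str
    classes: tuple[str, str] | None = None
    y_encoding: np.ndarray | None = None
    coef_y: np.ndarray | None = None  # per-component y-loadings c_a
    orth_scores: np.ndarray | None = None
    orth_loadings: np.ndarray | None = None
    orth_weights: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: float | None = None
    r2x_per_component: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def transform(self, X) -> np.ndarray:
        """Predictive scores for new samples (orthogonal variation removed)."""
        if self.kind == "pca":
            Xc = (_as_array(X) - self.x_mean) / self.x_scale
            return Xc @ self.loadings
        Xc = (_as_array(X) - self.x_mean) / self.x_scale
        if self.kind == "oplsda" and self.n_orth:
            for a in range(self.n_orth):
                t_o = Xc @ self.orth_weights[:, a]
                Xc = Xc - np.outer(t_o, self.orth_loadings[:, a])
            return (Xc @ self.weights)[:, :1]
        T = np.empty((Xc.shape[0], self.n_components))
        for a in range(self.n_components):
            T[:, a] = Xc @ self.weights[:, a]
            Xc = Xc - np.outer(T[:, a], self.loadings[:, a])
        return T

    def predict(self, X) -> np.ndarray:
        """Continuous class prediction on the {0, 1} encoding scale."""
        if self.kind == "pca":
            raise TypeError("PCA models do not predict a response")
        T = self.transform(X)
        return T @ self.coef_y[: T.shape[1]] + self.y_mean

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "n_components": self.n_components,
            "n_orth": self.n_orth,
            "scaling": self.scaling,
            "r2x": float(self.r2x),
            "r2y": None if self.r2y is None else float(self.r2y),
            "q2": None if self.q2 is None else float(self.q2),
            "classes": self.classes,
        }


def fit_pca(X, n_components: int, scaling: str = "uv") -> LatentModel:
    """PCA with deterministic sign convention (largest-|loading| element positive)."""
    Xa = _as_array(X)
    if n_components > min(Xa.shape[0] - 1, Xa.shape[1]):
        raise FitError(f"n_components={n_components} too large for shape {Xa.shape}")
    mean, scale = _scale_fit(Xa, scaling)
    Xc = (Xa - mean) / scale
    if not np.any(Xc.std(axis=0) > 0):
        raise FitError("matrix has zero variance everywhere")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xc)
    loadings = pca.components_.T.copy()
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    r2x_comp = pca.explained_variance_ratio_
    return LatentModel(
        kind="pca",
        scores=scores,
        loadings=loadings,
        weights=None,
        r2x=float(r2x_comp.sum()),
        r2y=None,
        q2=None,
        n_components=n_components,
        n_orth=0,
        scaling=scaling,
        x_mean=mean,
        x_scale=scale,
        r2x_per_component=r2x_comp,
    )


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS1 with X- and y-deflation; returns (T, W, P, c)."""
    n, p = Xc.shape
    T = np.empty((n, n_components))
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    c = np.empty(n_components)
    X = Xc.copy()
    y = yc.copy()
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise FitError(f"no X-y covariance left at component {a + 1}")
        w /= norm
        t = X @ w
        tt = t @ t
        if tt < 1e-12:
            raise FitError(f"degenerate score at component {a + 1}")
        P[:, a] = X.T @ t / tt
        c[a] = y @ t / tt
        T[:, a], W[:, a] = t, w
        X -= np.outer(t, P[:, a])
        y = y - c[a] * t
    return T, W, P, c


def _orient(T, W, P, c, y_enc):
    """Flip the first component so class 1 has positive mean score."""
    pos = T[y_enc == 1, 0].mean()
    if pos < 0:
        T[:, 0] *= -1
        W[:, 0] *= -1
        P[:, 0] *= -1
        c[0] *= -1
    return T, W, P, c


def fit_plsda(
    X,
    y,
    n_components: int = 2,
    scaling: str = "uv",
    cv_k: int = 7,
    compute_q2: bool = True,
) -> LatentModel:
    """Two-class PLS-DA; reports cumulative R2X/R2Y and stratified k-fold Q2."""
    Xa = _as_array(X)
    y_enc, classes = encode_labels(y)
    if len(y_enc) != Xa.shape[0]:
        raise FitError("X and y length mismatch")
    mean, scale = _scale_fit(Xa, scaling)
    Xc = (Xa - mean) / scale
    y_mean = y_enc.mean()
    yc = y_enc - y_mean
    ss_y = yc @ yc
    ss_x = np.sum(Xc**2)
    if ss_x <= 0:
        raise FitError("matrix has zero variance everywhere")

    T, W, P, c = _nipals_pls1(Xc, yc, n_components)
    T, W, P, c = _orient(T, W, P, c, y_enc)
    resid_y = yc - T @ c
    r2y = 1.0 - (resid_y @ resid_y) / ss_y
    r2x_comp = np.array([(T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a]) / ss_x for a in range(n_components)])

    model = LatentModel(
        kind="plsda",
        scores=T,
        loadings=P,
        weights=W,
        r2x=float(r2x_comp.sum()),
        r2y=float(r2y),
        q2=None,
        n_components=n_components,
        n_orth=0,
        scaling=scaling,
        classes=classes,
        y_encoding=y_enc,
        coef_y=c,
        x_mean=mean,
        x_scale=scale,
        y_mean=float(y_mean),
        r2x_per_component=r2x_comp,
    )
    if compute_q2:
        spec = {"kind": "plsda", "n_components": n_components, "scaling": scaling}
        model.q2 = cross_validate(spec, Xa, y, k=cv_k)
    return model


def fit_oplsda(
    X,
    y,
    n_orth: int = 1,
    scaling: str = "uv",
    cv_k: int = 7,
    compute_q2: bool = True,
) -> LatentModel:
    """OPLS-DA: remove `n_orth` y-orthogonal components, then fit one
    predictive component. With n_orth=0 this reduces exactly to
    one-component PLS-DA."""
    if n_orth < 0:
        raise ConfigError("n_orth must be >= 0")
    Xa = _as_array(X)
    y_enc, classes = encode_labels(y)
    if len(y_enc) != Xa.shape[0]:
        raise FitError("X and y length mismatch")
    mean, scale = _scale_fit(Xa, scaling)
    Xc = (Xa - mean) / scale
    y_mean = y_enc.mean()
    yc = y_enc - y_mean
    ss_y = yc @ yc
    ss_x = np.sum(Xc**2)
    if ss_x <= 0:
        raise FitError("matrix has zero variance everywhere")

    n, p = Xc.shape
    T_o = np.empty((n, n_orth))
    W_o = np.empty((p, n_orth))
    P_o = np.empty((p, n_orth))
    Xd = Xc.copy()
    for a in range(n_orth):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise FitError("no X-y covariance")
        w /= norm
        t = Xd @ w
        tt = t @ t
        p_load = Xd.T @ t / tt
        w_o = p_load - (w @ p_load) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-12:
            raise FitError(f"no orthogonal variation left at component {a + 1}")
        w_o /= norm_o
        t_o = Xd @ w_o
        tt_o = t_o @ t_o
        P_o[:, a] = Xd.T @ t_o / tt_o
        T_o[:, a], W_o[:, a] = t_o, w_o
        Xd -= np.outer(t_o, P_o[:, a])

    T, W, P, c = _nipals_pls1(Xd, yc, 1)
    T, W, P, c = _orient(T, W, P, c, y_enc)
    resid_y = yc - T @ c
    r2y = 1.0 - (resid_y @ resid_y) / ss_y
    r2x_pred = (T[:, 0] @ T[:, 0]) * (P[:, 0] @ P[:, 0]) / ss_x
    r2x_orth = sum(
        (T_o[:, a] @ T_o[:, a]) * (P_o[:, a] @ P_o[:, a]) / ss_x for a in range(n_orth)
    )

    model = LatentModel(
        kind="oplsda",
        scores=T,
        loadings=P,
        weights=W,
        r2x=float(r2x_pred + r2x_orth),
        r2y=float(r2y),
        q2=None,
        n_components=1,
        n_orth=n_orth,
        scaling=scaling,
        classes=classes,
        y_encoding=y_enc,
        coef_y=c,
        orth_scores=T_o,
        orth_loadings=P_o,
        orth_weights=W_o,
        x_mean=mean,
        x_scale=scale,
        y_mean=float(y_mean),
        r2x_per_component=np.array([r2x_pred]),
        extras={"r2x_orth": float(r2x_orth)},
    )
    if compute_q2:
        spec = {"kind": "oplsda", "n_orth": n_orth, "scaling": scaling}
        model.q2 = cross_validate(spec, Xa, y, k=cv_k)
    return model


def _fit_from_spec(spec: dict, X, y) -> LatentModel:
    kind = spec.get("kind", "oplsda")
    if kind == "plsda":
        return fit_plsda(
            X, y, n_components=spec.get("n_components", 1),
            scaling=spec.get("scaling", "uv"), compute_q2=False,
        )
    if kind == "oplsda":
        return fit_oplsda(
            X, y, n_orth=spec.get("n_orth", 1),
            scaling=spec.get("scaling", "uv"), compute_q2=False,
        )
    raise ConfigError(f"unknown model kind {kind!r}")


def spec_components(spec: dict) -> int:
    """Total latent components a model spec consumes (predictive + orthogonal)."""
    if spec.get("kind", "oplsda") == "oplsda":
        return 1 + spec.get("n_orth", 1)
    return spec.get("n_components", 1)


def spec_predictive_components(spec: dict) -> int:
    """Components that model the response (excludes orthogonal filters)."""
    if spec.get("kind", "oplsda") == "oplsda":
        return 1
    return spec.get("n_components", 1)


def cross_validate(
    modelspec: dict, X, y, k: int = 7, seed: int = DEFAULT_CV_SEED,
    return_press: bool = False,
):
    """Stratified k-fold Q2 = 1 - PRESS/SS around the mean-centered response."""
    if k < 2:
        raise FoldError("need at least 2 folds")
    Xa = _as_array(X)
    y = np.asarray(y)
    y_enc, _ = encode_labels(y)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise FoldError(f"k={k} exceeds smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    pred = np.empty(len(y_enc))
    for train, test in skf.split(Xa, y):
        model = _fit_from_spec(modelspec, Xa[train], y[train])
        pred[test] = model.predict(Xa[test])
    press = float(np.sum((y_enc - pred) ** 2))
    ss = float(np.sum((y_enc - y_enc.mean()) ** 2))
    q2 = 1.0 - press / ss
    if return_press:
        return q2, press, ss, pred
    return q2


class CvAnova(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class ValidationReport:
    """RPT permutation rows, regression intercepts, empirical p, CV-ANOVA."""

    permutation: pd.DataFrame  # columns: corr, r2y, q2
    rpt_intercepts: tuple[float, float]  # (R2Y, Q2) intercepts at |corr| = 0
    empirical_p: float
    r2y_observed: float
    q2_observed: float
    cv_anova: CvAnova | None = None


def permutation_test(
    X, y, n_perm: int = 200, seed: int = 0, modelspec: dict | None = None, k: int = 7
) -> ValidationReport:
    """Response permutation testing (RPT).

    Refits the model under `n_perm` random label permutations, keeping the
    unpermuted model's component count, and reports R2Y/Q2 regression
    intercepts against |corr(y_perm, y)| (observed model included as the
    corr=1 point) plus the exchangeability-exact empirical p-value
    (1 + #{Q2_perm >= Q2_obs}) / (n_perm + 1).
    """
    if n_perm < 20:
        raise ConfigError("n_perm must be >= 20")
    spec = modelspec or {"kind": "oplsda", "n_orth": 1, "scaling": "uv"}
    Xa = _as_array(X)
    y = np.asarray(y)
    y_enc, _ = encode_labels(y)

    obs = _fit_from_spec(spec, Xa, y)
    q2_obs = cross_validate(spec, Xa, y, k=k)
    r2y_obs = obs.r2y

    rng = np.random.default_rng(seed)
    sd_y = y_enc.std()
    rows = []
    for _ in range(n_perm):
        perm = rng.permutation(len(y))
        y_p = y[perm]
        corr = abs(float(np.mean((y_enc - y_enc.mean()) * (y_enc[perm] - y_enc.mean())) / sd_y**2))
        model_p = _fit_from_spec(spec, Xa, y_p)
        q2_p = cross_validate(spec, Xa, y_p, k=k)
        rows.append((corr, model_p.r2y, q2_p))
    table = pd.DataFrame(rows, columns=["corr", "r2y", "q2"])

    xs = np.concatenate([table["corr"].to_numpy(), [1.0]])
    r2_int = float(np.polyfit(xs, np.concatenate([table["r2y"], [r2y_obs]]), 1)[1])
    q2_int = float(np.polyfit(xs, np.concatenate([table["q2"], [q2_obs]]), 1)[1])
    emp_p = (1 + int((table["q2"] >= q2_obs).sum())) / (n_perm + 1)

    return ValidationReport(
        permutation=table,
        rpt_intercepts=(r2_int, q2_int),
        empirical_p=emp_p,
        r2y_observed=float(r2y_obs),
        q2_observed=float(q2_obs),
    )


def cv_anova(
    X, y, modelspec: dict | None = None, k: int = 7, seed: int = DEFAULT_CV_SEED
) -> CvAnova:
    """F-test of cross-validated residuals against total response variation.

    F = ((SS - PRESS)/df1) / (PRESS/df2) with df1 = number of predictive
    components (only those model the response; orthogonal filters do not)
    and df2 = N - 1 - total components fitted (orthogonal filters still
    consume residual degrees of freedom). A model whose CV residuals exceed
    the total variation (PRESS >= SS) is reported as p = 1, never as
    significant.
    """
    spec = modelspec or {"kind": "oplsda", "n_orth": 1, "scaling": "uv"}
    _, press, ss, _ = cross_validate(spec, X, y, k=k, seed=seed, return_press=True)
    n = len(np.asarray(y))
    df1 = spec_predictive_components(spec)
    df2 = n - 1 - spec_components(spec)
    if df2 < 1:
        raise FitError("too few samples for CV-ANOVA degrees of freedom")
    if press == 0.0:  # perfect cross-validated prediction
        return CvAnova(float("inf"), df1, df2, 0.0)
    if press >= ss:
        return CvAnova(0.0, df1, df2, 1.0)
    F = ((ss - press) / df1) / (press / df2)
    p = float(stats.f.sf(F, df1, df2))
    return CvAnova(float(F), df1, df2, p)


def vip(model: LatentModel) -> np.ndarray:
    """Variable importance in the projection.

    VIP_j = sqrt(p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a) over the
    predictive components, where SSY_a = c_a^2 t_a't_a is the response
    variation explained by component a. mean(VIP^2) = 1 by construction.
    """
    if model.kind not in ("plsda", "oplsda"):
        raise TypeError(f"VIP requires a PLS-DA or OPLS-DA model, got {model.kind}")
    W, T, c = model.weights, model.scores, model.coef_y
    p = W.shape[0]
    A = model.n_components
    ssy = np.array([c[a] ** 2 * (T[:, a] @ T[:, a]) for a in range(A)])
    wn2 = np.array([(W[:, a] / np.linalg.norm(W[:, a])) ** 2 for a in range(A)]).T
    return np.sqrt(p * (wn2 @ ssy) / ssy.sum())


def save_model(model: LatentModel, path) -> None:
    """Serialize a fitted model to JSON (arrays stored as lists)."""
    import json

    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    payload = {
        "kind": model.kind,
        "n_components": model.n_components,
        "n_orth": model.n_orth,
        "scaling": model.scaling,
        "r2x": model.r2x,
        "r2y": model.r2y,
        "q2": model.q2,
        "classes": model.classes,
        "scores": arr(model.scores),
        "loadings": arr(model.loadings),
        "weights": arr(model.weights),
        "coef_y": arr(model.coef_y),
        "y_encoding": arr(model.y_encoding),
        "orth_scores": arr(model.orth_scores),
        "orth_loadings": arr(model.orth_loadings),
        "orth_weights": arr(model.orth_weights),
        "x_mean": arr(model.x_mean),
        "x_scale": arr(model.x_scale),
        "y_mean": model.y_mean,
        "r2x_per_component": arr(model.r2x_per_component),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> LatentModel:
    import json

    with open(path) as fh:
        payload = json.load(fh)

    def arr(key):
        v = payload[key]
        return None if v is None else np.asarray(v, dtype=float)

    return LatentModel(
        kind=payload["kind"],
        scores=arr("scores"),
        loadings=arr("loadings"),
        weights=arr("weights"),
        r2x=payload["r2x"],
        r2y=payload["r2y"],
        q2=payload["q2"],
        n_components=payload["n_components"],
        n_orth=payload["n_orth"],
        scaling=payload["scaling"],
        classes=None if payload["classes"] is None else tuple(payload["classes"]),
        y_encoding=arr("y_encoding"),
        coef_y=arr("coef_y"),
        orth_scores=arr("orth_scores"),
        orth_loadings=arr("orth_loadings"),
        orth_weights=arr("orth_weights"),
        x_mean=arr("x_mean"),
        x_scale=arr("x_scale"),
        y_mean=payload["y_mean"],
        r2x_per_component=arr("r2x_per_component"),
    )


class CorrelationLoadings(NamedTuple):
    r: np.ndarray
    undefined: np.ndarray  # True where the variable had zero variance


def correlation_loadings(model: LatentModel, X) -> CorrelationLoadings:
    """Pearson correlation of each variable with the predictive score tp1.

    Zero-variance variables get r = 0 and are flagged in `undefined`.
    """
    if model.kind == "pca":
        raise TypeError("correlation loadings require a supervised model")
    Xa = _as_array(X)
    t = model.scores[:, 0]
    tc = t - t.mean()
    nt = np.linalg.norm(tc)
    Xc = Xa - Xa.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    undefined = norms <= 1e-12
    safe = np.where(undefined, 1.0, norms)
    r = (Xc.T @ tc) / (safe * nt)
    r[undefined] = 0.0
    return CorrelationLoadings(r=np.clip(r, -1.0, 1.0), undefined=undefined)
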