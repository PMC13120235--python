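"""NIPALS PLS1 regression and its binary discriminant wrapper (PLS-DA).

PLS projects the spectra onto a small number of latent variables chosen to
maximise covariance with the response, then regresses the response on the
scores.  The single-response NIPALS recursion used here is, per component::

    w = X'y / ||X'y||        (unit weight vector)
    t = X w                  (score)
    p = X't / (t't)          (x-loading)
    q = y't / (t't)          (y-loading)
    X <- X - t p',  y <- y - t q     (deflation)

X and y are always mean-centred inside the model (after any pre-treatment),
and the folded-back coefficient form is ``b = W (P'W)^-1 q`` with intercept
``y_mean - x_mean' b``.  PLS-DA encodes the two classes as 0/1 and thresholds
the predicted response at 0.5 (strictly greater than 0.5 is positive).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from .io import ValidationError
from .preprocess import FittedPretreatment, PretreatmentSpec

MODEL_FORMAT = "blendspec-model/1"


class PLS1Regression(RegressorMixin, BaseEstimator):
    """Single-response partial least squares via NIPALS.

    Parameters
    ----------
    n_components : requested number of latent variables (must not exceed
        ``min(n_samples - 1, n_channels)``).
    deflation_tol : relative tolerance below which the residual covariance
        ``X'y`` is considered exhausted; extraction then stops early with a
        warning and ``n_components_ < n_components``.

    Fitted attributes
    -----------------
    x_weights_ : (p, a) unit-norm weight vectors W
    x_loadings_ : (p, a) loadings P
    y_loadings_ : (a,) loadings q
    x_scores_ : (n, a) training scores (mutually orthogonal)
    x_mean_, y_mean_ : centring statistics
    coef_, intercept_ : folded-back regression vector and intercept
    n_components_ : latent variables actually extracted
    y_deflated_early_ : True when extraction stopped before the request
    """

    def __init__(self, n_components: int = 2, deflation_tol: float = 1e-12):
        self.n_components = n_components
        self.deflation_tol = deflation_tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValidationError(f"{y.size} responses for {n} samples")
        a_req = int(self.n_components)
        if a_req < 1:
            raise ValidationError("n_components must be >= 1")
        if a_req > min(n - 1, p):
            raise ValidationError(
                f"n_components={a_req} exceeds min(n_samples - 1, n_channels)"
                f" = {min(n - 1, p)}"
            )
        if np.std(y) == 0.0:
            raise ValidationError("response has zero variance")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        s0 = float(np.linalg.norm(Xc.T @ yc))

        W, P, Q, T = [], [], [], []
        self.y_deflated_early_ = False
        for _ in range(a_req):
            s = Xc.T @ yc
            ns = float(np.linalg.norm(s))
            if ns <= self.deflation_tol * max(s0, 1.0):
                self.y_deflated_early_ = True
                warnings.warn(
                    f"response fully deflated after {len(W)} of {a_req} "
                    "latent variables",
                    stacklevel=2,
                )
                break
            w = s / ns
            t = Xc @ w
            tt = float(t @ t)
            if tt <= 0.0:
                self.y_deflated_early_ = True
                break
            p_a = (Xc.T @ t) / tt
            q_a = float(yc @ t) / tt
            Xc = Xc - np.outer(t, p_a)
            yc = yc - q_a * t
            W.append(w)
            P.append(p_a)
            Q.append(q_a)
            T.append(t)
        if not W:
            raise ValidationError("could not extract any latent variable")

        self.x_weights_ = np.column_stack(W)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.asarray(Q)
        self.x_scores_ = np.column_stack(T)
        self.n_components_ = len(W)
        self.n_features_in_ = p
        self.coef_ = self._coef(self.n_components_)
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        return self

    def _coef(self, a: int) -> np.ndarray:
        W = self.x_weights_[:, :a]
        P = self.x_loadings_[:, :a]
        q = self.y_loadings_[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def _check_width(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"{X.shape[1]} channels but model was fitted on "
                f"{self.n_features_in_}"
            )
        return X

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        """Predicted response; ``n_components`` truncates the model."""
        X = self._check_width(X)
        if n_components is None:
            b = self.coef_
        else:
            if not 1 <= n_components <= self.n_components_:
                raise ValidationError(
                    f"n_components must lie in [1, {self.n_components_}]"
                )
            b = self._coef(n_components)
        return (X - self.x_mean_) @ b + self.y_mean_

    def predict_path(self, X) -> np.ndarray:
        """Predictions for every truncation 1..n_components_ at once,
        shape ``(n_samples, n_components_)`` — used by the CV engine."""
        X = self._check_width(X)
        Xc = X - self.x_mean_
        out = np.empty((X.shape[0], self.n_components_))
        cum = np.full(X.shape[0], self.y_mean_)
        for a in range(self.n_components_):
            t = Xc @ self.x_weights_[:, a]
            Xc = Xc - np.outer(t, self.x_loadings_[:, a])
            cum = cum + self.y_loadings_[a] * t
            out[:, a] = cum
        return out


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Binary PLS discriminant analysis: one targeted class against the rest.

    The class membership vector is encoded positive -> 1, negative -> 0, a
    PLS1 model is fitted on the encoding and a sample is called positive iff
    its predicted response is strictly greater than ``threshold`` (0.5 lies
    symmetrically between the encoded values).
    """

    def __init__(self, n_components: int = 2, threshold: float = 0.5,
                 positive_label: str | None = None):
        self.n_components = n_components
        self.threshold = threshold
        self.positive_label = positive_label

    def fit(self, X, y):
        y = np.asarray(y)
        if y.dtype != bool:
            uniq = np.unique(y)
            if not np.isin(uniq, [0, 1]).all():
                raise ValidationError(
                    "labels must be boolean or 0/1 membership indicators"
                )
            y = y.astype(bool)
        if y.all() or not y.any():
            raise ValidationError("both classes must be present for PLS-DA")
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("threshold must lie strictly between 0 and 1")
        self.pls_ = PLS1Regression(self.n_components).fit(X, y.astype(float))
        self.classes_ = np.array([False, True])
        self.n_components_ = self.pls_.n_components_
        self.n_features_in_ = self.pls_.n_features_in_
        return self

    def decision_function(self, X, n_components: int | None = None) -> np.ndarray:
        """Continuous predicted response on the 0/1 encoding scale."""
        return self.pls_.predict(X, n_components)

    def decision_path(self, X) -> np.ndarray:
        return self.pls_.predict_path(X)

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        return self.decision_function(X, n_components) > self.threshold


# ----------------------------------------------------------------------
# thin functional wrappers over the estimators

def pls1_fit(x, y, n_lv: int) -> PLS1Regression:
    return PLS1Regression(n_components=n_lv).fit(x, y)


def pls_predict(m: PLS1Regression, x) -> np.ndarray:
    return m.predict(x)


def plsda_fit(x, labels, n_lv: int, positive_label: str | None = None
              ) -> PLSDAClassifier:
    return PLSDAClassifier(n_components=n_lv, positive_label=positive_label).fit(
        x, labels
    )


def plsda_predict(m: PLSDAClassifier, x) -> tuple[np.ndarray, np.ndarray]:
    scores = m.decision_function(x)
    return scores > m.threshold, scores


# ----------------------------------------------------------------------
# serialization: flat JSON, versioned, full float precision

def _arr(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def _pretreatment_to_dict(fp: FittedPretreatment | None) -> dict | None:
    if fp is None:
        return None
    return {
        "spec": asdict(fp.spec),
        "input_grid": _arr(fp.input_grid),
        "retained_grid": _arr(fp.retained_grid),
        "column_means": None if fp.column_means is None else _arr(fp.column_means),
        "column_sds": None if fp.column_sds is None else _arr(fp.column_sds),
    }


def _pretreatment_from_dict(d: dict | None) -> FittedPretreatment | None:
    if d is None:
        return None
    return FittedPretreatment(
        PretreatmentSpec(**d["spec"]),
        np.asarray(d["input_grid"]),
        np.asarray(d["retained_grid"]),
        None if d["column_means"] is None else np.asarray(d["column_means"]),
        None if d["column_sds"] is None else np.asarray(d["column_sds"]),
    )


def save_model_bundle(path, model, pretreatment: FittedPretreatment | None = None
                      ) -> None:
    """Serialize a fitted PLS1/PLS-DA model plus its pre-treatment to JSON."""
    if isinstance(model, PLSDAClassifier):
        kind, core = "plsda", model.pls_
        extra = {"threshold": model.threshold,
                 "positive_label": model.positive_label}
    elif isinstance(model, PLS1Regression):
        kind, core = "pls1", model
        extra = {}
    else:
        raise ValidationError(f"cannot serialize {type(model).__name__}")
    doc = {
        "format": MODEL_FORMAT,
        "kind": kind,
        **extra,
        "n_components": core.n_components_,
        "x_weights": _arr(core.x_weights_),
        "x_loadings": _arr(core.x_loadings_),
        "y_loadings": _arr(core.y_loadings_),
        "x_mean": _arr(core.x_mean_),
        "y_mean": core.y_mean_,
        "pretreatment": _pretreatment_to_dict(pretreatment),
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_model_bundle(path):
    """Inverse of :func:`save_model_bundle`.

    Returns ``(model, fitted_pretreatment_or_None)``.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != MODEL_FORMAT:
        raise ValidationError(f"unsupported model format {doc.get('format')!r}")
    core = PLS1Regression(n_components=doc["n_components"])
    core.x_weights_ = np.asarray(doc["x_weights"])
    core.x_loadings_ = np.asarray(doc["x_loadings"])
    core.y_loadings_ = np.asarray(doc["y_loadings"])
    core.x_scores_ = None
    core.x_mean_ = np.asarray(doc["x_mean"])
    core.y_mean_ = float(doc["y_mean"])
    core.n_components_ = int(doc["n_components"])
    core.n_features_in_ = core.x_weights_.shape[0]
    core.y_deflated_early_ = False
    core.coef_ = core._coef(core.n_components_)
    core.intercept_ = core.y_mean_ - float(core.x_mean_ @ core.coef_)
    if doc["kind"] == "plsda":
        model = PLSDAClassifier(
            n_components=core.n_components_,
            threshold=doc["threshold"],
            positive_label=doc["positive_label"],
        )
        model.pls_ = core
        model.classes_ = np.array([False, True])
        model.n_components_ = core.n_components_
        model.n_features_in_ = core.n_features_in_
    else:
        model = core
    return model, _pretreatment_from_dict(doc["pretreatment"])
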