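"""Model evaluation: cross-validation, complexity and pre-treatment
selection, classification/regression metrics and limit-of-detection.

Complexity (the latent-variable count) is selected by 10-fold
cross-validation on the training set: the RMSECV minimiser, with ties going
to the less complex model.  The best pre-treatment per variety is then
selected primarily on the external test criterion (RMSEP for regression,
test-set CCR for classification); only ties there — equality after rounding
to 4 decimals — fall back to the cross-validation criterion and finally to
the smaller latent-variable count.  Selecting on the external test set
follows the original study design and is statistically optimistic: the test
criterion of the winning recipe is no longer a fully independent estimate.

Regression quality is additionally summarised by RPD (SD of the test
references over RMSEP) and RER (range of the test references over RMSEP)
with the conventional interpretation bands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpectraSet, ValidationError
from .pls import PLS1Regression, PLSDAClassifier
from .preprocess import (
    FittedPretreatment,
    PretreatmentSpec,
    apply_pretreatment,
    default_specs,
)

_TIE_ATOL = 1e-12       # RMSECV ties during LV selection
_TIE_DECIMALS = 4       # "similar RMSEP" tie rule during recipe selection


# ----------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ClassMetrics:
    """Confusion counts and the derived rates.

    ``ccr`` is a percentage; precision, specificity and sensitivity are
    fractions.  Ratios with a zero denominator are NaN (with a warning),
    never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    ccr: float
    precision: float
    specificity: float
    sensitivity: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return math.nan
    return num / den


def classification_metrics(y_true, y_pred) -> ClassMetrics:
    """Confusion-matrix summary of binary predictions."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise ValidationError("need at least one sample")
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    n = y_true.size
    return ClassMetrics(
        tp, fp, tn, fn,
        ccr=100.0 * (tp + tn) / n,
        precision=_ratio(tp, tp + fp, "precision"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
    )


@dataclass(frozen=True)
class RegMetrics:
    """External-test regression summary.

    ``rmsep`` is in proportion percentage units; ``r2p`` is the squared
    Pearson correlation of predicted vs reference; RPD = SD(references,
    n-1)/RMSEP and RER = range(references)/RMSEP, with qualitative bands.
    A perfect fit gives RMSEP 0 and infinite RPD/RER.
    """

    rmsep: float
    r2p: float
    rpd: float
    rer: float
    rpd_band: str
    rer_band: str


def _rpd_band(r: float) -> str:
    if r < 1.5:
        return "poor"
    if r < 2.0:
        return "rough screening"
    if r < 2.5:
        return "approximate"
    if r < 3.0:
        return "good"
    return "excellent"


def _rer_band(r: float) -> str:
    if r < 5.0:
        return "poor"
    if r <= 10.0:
        return "acceptable"
    return "excellent"


def regression_metrics(y_true, y_pred) -> RegMetrics:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred lengths differ")
    if y_true.size < 2:
        raise ValidationError("need at least two samples")
    sd = float(np.std(y_true, ddof=1))
    if sd == 0.0:
        raise ValidationError("reference values have zero variance")
    rmsep = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    if rmsep == 0.0:
        rpd = rer = math.inf
        r2p = 1.0
    else:
        rpd = sd / rmsep
        rer = float(np.ptp(y_true)) / rmsep
        r2p = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    return RegMetrics(rmsep, r2p, rpd, rer, _rpd_band(rpd), _rer_band(rer))


# ----------------------------------------------------------------------
# fold assignment and cross-validation

def assign_folds(n: int, k: int, labels=None, seed: int = 0) -> np.ndarray:
    """Seeded fold assignment: shuffle, then contiguous blocks of size
    ceil(n/k) or floor(n/k).

    With binary ``labels`` the assignment is stratified: positives are dealt
    round-robin so every fold's positive count is within one of exact
    proportionality, avoiding single-class folds on near-balanced sets.
    """
    if not 1 <= k <= n:
        raise ValidationError(f"need 1 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    n_big = n % k
    sizes = [n // k + 1] * n_big + [n // k] * (k - n_big)
    out = np.empty(n, dtype=int)
    if labels is None:
        perm = rng.permutation(n)
        start = 0
        for f, size in enumerate(sizes):
            out[perm[start:start + size]] = f
            start += size
        return out
    labels = np.asarray(labels).astype(bool)
    if labels.size != n:
        raise ValidationError("labels length must equal n")
    pos = rng.permutation(np.flatnonzero(labels))
    neg = rng.permutation(np.flatnonzero(~labels))
    capacity = list(sizes)
    fold_of = np.empty(n, dtype=int)
    f = 0
    for idx in pos:
        while capacity[f % k] == 0:
            f += 1
        fold_of[idx] = f % k
        capacity[f % k] -= 1
        f += 1
    f = 0
    for idx in neg:
        while capacity[f % k] == 0:
            f += 1
        fold_of[idx] = f % k
        capacity[f % k] -= 1
        f += 1
    return fold_of


@dataclass(eq=False)
class CVResult:
    """Pooled cross-validation predictions and derived criteria.

    ``rmsecv_per_lv[a-1]`` is the RMSECV using ``a`` latent variables;
    ``ccr_per_lv`` is populated for classification only.  The pooled
    prediction matrix allows any further metric to be computed at the
    selected complexity without re-running CV.
    """

    rmsecv_per_lv: np.ndarray
    fold_assignment: np.ndarray
    cv_predictions: np.ndarray  # (n, max_lv)
    y: np.ndarray
    task: str
    ccr_per_lv: np.ndarray | None = None

    @property
    def max_lv(self) -> int:
        return self.rmsecv_per_lv.size

    def r2_at(self, n_lv: int) -> float:
        """Squared correlation of pooled CV predictions vs reference."""
        return float(
            np.corrcoef(self.y, self.cv_predictions[:, n_lv - 1])[0, 1] ** 2
        )

    def rmsecv_at(self, n_lv: int) -> float:
        return float(self.rmsecv_per_lv[n_lv - 1])

    def class_metrics_at(self, n_lv: int, threshold: float = 0.5) -> ClassMetrics:
        if self.task != "classification":
            raise ValidationError("class metrics only defined for classification")
        return classification_metrics(
            self.y.astype(bool), self.cv_predictions[:, n_lv - 1] > threshold
        )


def cross_validate(
    spectra: SpectraSet,
    y,
    spec: PretreatmentSpec,
    max_lv: int,
    *,
    n_folds: int = 10,
    seed: int = 0,
    task: str = "regression",
) -> CVResult:
    """k-fold cross-validation with per-fold refitting of the pre-treatment.

    Every fold re-fits the statistics-bearing pre-treatment step and the PLS
    model on its own training part only, then predicts its held-out part for
    every latent-variable count up to ``max_lv``; held-out predictions are
    pooled over folds before computing RMSECV (and CCR for classification).
    Should extraction stop early on some fold (response fully deflated), the
    last available prediction is carried forward to the larger counts.
    """
    if task not in ("regression", "classification"):
        raise ValidationError(f"unknown task {task!r}")
    if max_lv < 1:
        raise ValidationError("max_lv must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    n = spectra.n_samples
    if y.size != n:
        raise ValidationError("response length must equal number of spectra")

    labels = y.astype(bool) if task == "classification" else None
    folds = assign_folds(n, n_folds, labels, seed)
    if task == "classification":
        # a training part with a single class cannot be modelled: one
        # re-seeded retry, then give up
        for attempt in range(2):
            bad = any(
                len(np.unique(labels[folds != f])) < 2 for f in range(n_folds)
            )
            if not bad:
                break
            if attempt == 1:
                raise ValidationError(
                    "single-class training part in cross-validation"
                )
            folds = assign_folds(n, n_folds, labels, seed + 1)

    p_eff = spectra.n_channels - (spec.sg_window - 1 if spec.deriv_order else 0)
    a_cap = max_lv
    for f in range(n_folds):
        n_tr = int(np.sum(folds != f))
        a_cap = min(a_cap, n_tr - 1, p_eff)
    if a_cap < 1:
        raise ValidationError("no latent variable extractable in some fold")

    cv_pred = np.empty((n, a_cap))
    for f in range(n_folds):
        tr = np.flatnonzero(folds != f)
        te = np.flatnonzero(folds == f)
        train_s = spectra.select(tr)
        test_s = spectra.select(te)
        tr2, (te2,), _ = apply_pretreatment(spec, train_s, [test_s])
        model = PLS1Regression(n_components=a_cap)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(tr2.absorbance, y[tr])
        path = model.predict_path(te2.absorbance)
        if path.shape[1] < a_cap:  # early stop: carry last prediction forward
            pad = np.repeat(path[:, -1:], a_cap - path.shape[1], axis=1)
            path = np.hstack([path, pad])
        cv_pred[te] = path

    rmsecv = np.sqrt(np.mean((cv_pred - y[:, None]) ** 2, axis=0))
    ccr = None
    if task == "classification":
        ccr = 100.0 * np.mean((cv_pred > 0.5) == labels[:, None], axis=0)
    return CVResult(rmsecv, folds, cv_pred, y, task, ccr)


def select_n_latent(cv) -> int:
    """RMSECV minimiser; ties within 1e-12 go to the less complex model."""
    rmsecv = np.asarray(cv.rmsecv_per_lv if isinstance(cv, CVResult) else cv,
                        dtype=float)
    if rmsecv.size == 0:
        raise ValidationError("empty RMSECV vector")
    best = rmsecv.min()
    return int(np.flatnonzero(rmsecv <= best + _TIE_ATOL)[0]) + 1


# ----------------------------------------------------------------------
# pre-treatment sweep

@dataclass(eq=False)
class SweepEntry:
    """One fitted candidate (recipe, complexity, model, criteria)."""

    spec: PretreatmentSpec
    n_lv: int
    model: object
    pretreatment: FittedPretreatment
    cv: CVResult
    test_metrics: object  # RegMetrics or ClassMetrics
    y_test_pred: np.ndarray


@dataclass(eq=False)
class SelectionReport:
    """Per-recipe results for one variety, mirroring a model-selection table.

    ``table`` has one row per pre-treatment; ``chosen`` names the winning
    recipe under the documented selection rule.
    """

    task: str
    table: pd.DataFrame
    chosen: str
    entries: dict = field(default_factory=dict)

    @property
    def chosen_entry(self) -> SweepEntry:
        return self.entries[self.chosen]


def _effective_max_lv(max_lv: int, n_train: int, n_folds: int) -> int:
    return max(1, min(max_lv, n_train - math.ceil(n_train / n_folds) - 1))


def sweep_pretreatments(
    train: SpectraSet,
    test: SpectraSet,
    y_train,
    y_test,
    specs=None,
    *,
    task: str = "regression",
    max_lv: int = 15,
    n_folds: int = 10,
    seed: int = 0,
) -> SelectionReport:
    """Fit and evaluate all candidate pre-treatments for one response.

    For each recipe: 10-fold CV on the training set selects the
    latent-variable count, the final model is refitted on the full training
    set and scored on the external test set.  The winner minimises RMSEP
    (regression) or maximises test CCR (classification); ties after rounding
    to 4 decimals fall back to the CV criterion, then to fewer latent
    variables, then to recipe order.
    """
    if specs is None:
        specs = default_specs()
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_test = np.asarray(y_test, dtype=float).ravel()
    shared = set(train.sample_ids) & set(test.sample_ids)
    if shared:
        raise ValidationError(f"train and test sets overlap: {sorted(shared)[:3]}")
    a_max = _effective_max_lv(max_lv, train.n_samples, n_folds)

    rows = []
    entries = {}
    for spec in specs:
        cv = cross_validate(
            train, y_train, spec, a_max, n_folds=n_folds, seed=seed, task=task
        )
        n_lv = select_n_latent(cv)
        tr2, (te2,), fitted = apply_pretreatment(spec, train, [test])
        if task == "regression":
            model = PLS1Regression(n_components=n_lv).fit(tr2.absorbance, y_train)
            y_hat = model.predict(te2.absorbance)
            tm = regression_metrics(y_test, y_hat)
            rows.append({
                "pretreatment": spec.name,
                "n_lv": n_lv,
                "rmsep": tm.rmsep,
                "r2p": tm.r2p,
                "rpd": tm.rpd,
                "rer": tm.rer,
                "rmsecv": cv.rmsecv_at(n_lv),
                "r2cv": cv.r2_at(n_lv),
            })
        else:
            model = PLSDAClassifier(n_components=n_lv).fit(
                tr2.absorbance, y_train.astype(bool)
            )
            y_hat = model.predict(te2.absorbance)
            tm = classification_metrics(y_test.astype(bool), y_hat)
            cm_cv = cv.class_metrics_at(n_lv)
            rows.append({
                "pretreatment": spec.name,
                "n_lv": n_lv,
                "ccr_test": tm.ccr,
                "ccr_cv": cm_cv.ccr,
                "precision_test": tm.precision,
                "specificity_test": tm.specificity,
                "sensitivity_test": tm.sensitivity,
                "precision_cv": cm_cv.precision,
                "specificity_cv": cm_cv.specificity,
                "sensitivity_cv": cm_cv.sensitivity,
            })
        entries[spec.name] = SweepEntry(spec, n_lv, model, fitted, cv, tm, y_hat)

    table = pd.DataFrame(rows)
    if task == "regression":
        keys = [
            (round(r["rmsep"], _TIE_DECIMALS), round(r["rmsecv"], _TIE_DECIMALS),
             r["n_lv"], i)
            for i, r in enumerate(rows)
        ]
    else:
        keys = [
            (-round(r["ccr_test"], _TIE_DECIMALS), -round(r["ccr_cv"], _TIE_DECIMALS),
             r["n_lv"], i)
            for i, r in enumerate(rows)
        ]
    chosen = rows[min(keys)[-1]]["pretreatment"]
    return SelectionReport(task, table, chosen, entries)


# ----------------------------------------------------------------------
# limit of detection

@dataclass(frozen=True)
class LODResult:
    """Outcome of classifying a trituration (spike) series.

    ``lod`` is the smallest level from which all higher levels are also
    positive (monotone-tail rule); isolated positives below it are kept in
    ``positive_flags`` but do not lower the LOD.  ``label`` renders either
    the level (e.g. ``"1%"``) or ``">8%"`` when no level qualifies.
    """

    variety: str
    levels_tested: tuple
    positive_flags: tuple
    lod: float | None
    label: str


def estimate_lod(
    model,
    fitted_pretreatment: FittedPretreatment | None,
    trituration_spectra: SpectraSet,
    levels,
    variety: str = "",
) -> LODResult:
    """Classify one spike series (one spectrum per ascending level) and read
    off the approximate limit of detection."""
    levels = tuple(float(v) for v in levels)
    if list(levels) != sorted(levels):
        raise ValidationError("levels must be sorted ascending")
    if trituration_spectra.n_samples != len(levels):
        raise ValidationError("one spectrum required per level")
    s = trituration_spectra
    if fitted_pretreatment is not None:
        s = fitted_pretreatment.transform(s)
    flags = np.asarray(model.predict(s.absorbance)).astype(bool)
    lod = None
    for i in range(len(levels)):
        if flags[i:].all():
            lod = levels[i]
            break
    label = f"{lod:g}%" if lod is not None else f">{levels[-1]:g}%"
    return LODResult(variety, levels, tuple(bool(b) for b in flags), lod, label)
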