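"""Spectral pre-treatments: SNV, Savitzky-Golay derivatives, autoscaling.

Six recipes are explored ahead of PLS modelling, named exactly as they appear
in configuration files and reports::

    autoscale, snv, d1, d2, snv_d1, snv_d2

SNV and the derivatives are *sample-local* (each output row depends only on
its own input row); autoscaling carries training statistics and is therefore
fitted on the training set only and applied unchanged to validation data.
Derivatives are expressed per cm^-1 and truncate the half-window edges, so a
window of 17 removes 16 channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_coeffs
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SpectraSet, ValidationError

#: the six recipe names, in canonical report order
PRETREATMENTS = ("autoscale", "snv", "d1", "d2", "snv_d1", "snv_d2")

_SD_FLOOR = 1e-12  # channel SDs below this are treated as zero-variance


@dataclass(frozen=True)
class PretreatmentSpec:
    """One pre-treatment recipe.

    ``sg_window``/``sg_polyorder`` only matter for the derivative-containing
    recipes; the defaults (window 17, second-order polynomial) are the
    settings used throughout.
    """

    name: str
    sg_window: int = 17
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.name not in PRETREATMENTS:
            raise ValidationError(
                f"unknown pre-treatment {self.name!r}; expected one of {PRETREATMENTS}"
            )
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValidationError(
                "sg_window must be odd and greater than sg_polyorder"
            )

    @property
    def deriv_order(self) -> int:
        return {"d1": 1, "snv_d1": 1, "d2": 2, "snv_d2": 2}.get(self.name, 0)

    @property
    def uses_snv(self) -> bool:
        return self.name in ("snv", "snv_d1", "snv_d2")

    @property
    def uses_autoscale(self) -> bool:
        return self.name == "autoscale"


def default_specs(sg_window: int = 17, sg_polyorder: int = 2) -> list[PretreatmentSpec]:
    """The six recipes with shared Savitzky-Golay settings."""
    return [PretreatmentSpec(n, sg_window, sg_polyorder) for n in PRETREATMENTS]


# ----------------------------------------------------------------------
# array-level transformers (sklearn estimator API)

class SNVScaler(TransformerMixin, BaseEstimator):
    """Standard normal variate: centre and scale every spectrum (row) to
    mean 0, SD 1 (SD with n-1 denominator).

    Removes per-sample multiplicative scatter and offset; stateless, so
    ``fit`` only records the input width.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] < 2:
            raise ValidationError("SNV needs at least 2 channels")
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        flat = np.flatnonzero(sd.ravel() <= 0.0)
        if flat.size:
            raise ValidationError(
                f"constant spectrum at row {flat[0]}: SNV undefined"
            )
        return (X - mean) / sd


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Least-squares local-polynomial derivative of each spectrum.

    Parameters
    ----------
    deriv : 1 or 2
    window : odd window length in channels
    polyorder : fitted polynomial order (must be >= deriv and < window)
    delta : channel spacing in cm^-1, so output units are per cm^-1
        (making results invariant to the grid resolution)

    Edge channels lacking a full window are dropped: output has
    ``n_channels - (window - 1)`` columns.
    """

    def __init__(self, deriv: int = 1, window: int = 17, polyorder: int = 2,
                 delta: float = 1.0):
        self.deriv = deriv
        self.window = window
        self.polyorder = polyorder
        self.delta = delta

    def _validate(self):
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValidationError("window must be odd and greater than polyorder")
        if not 1 <= self.deriv <= self.polyorder:
            raise ValidationError("need 1 <= deriv <= polyorder")
        if self.delta <= 0:
            raise ValidationError("delta must be positive")

    def fit(self, X, y=None):
        self._validate()
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        self._validate()
        X = np.asarray(X, dtype=float)
        if X.shape[1] < self.window:
            raise ValidationError(
                f"{X.shape[1]} channels is fewer than window {self.window}"
            )
        c = savgol_coeffs(self.window, self.polyorder, deriv=self.deriv,
                          delta=self.delta, use="dot")
        return sliding_window_view(X, self.window, axis=1) @ c


class Autoscaler(TransformerMixin, BaseEstimator):
    """Per-channel centring and unit-variance scaling with training statistics.

    SDs use the n-1 denominator.  Channels whose training SD is (numerically)
    zero carry no information and map to 0 rather than raising.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValidationError("autoscaling needs at least 2 training samples")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.size:
            raise ValidationError(
                f"{X.shape[1]} channels but scaler was fitted on {self.mean_.size}"
            )
        live = self.scale_ > _SD_FLOOR
        out = np.zeros_like(X)
        out[:, live] = (X[:, live] - self.mean_[live]) / self.scale_[live]
        return out


# ----------------------------------------------------------------------
# SpectraSet-level operations

def snv_transform(s: SpectraSet) -> SpectraSet:
    """SNV on a :class:`SpectraSet`; a constant spectrum is rejected with the
    offending sample id."""
    try:
        values = SNVScaler().fit_transform(s.absorbance)
    except ValidationError as err:
        msg = str(err)
        if "row" in msg:
            row = int(msg.split("row ")[1].split(":")[0])
            raise ValidationError(
                f"constant spectrum for sample {s.sample_ids[row]!r}: SNV undefined"
            ) from None
        raise
    return SpectraSet(s.grid, values, list(s.sample_ids), dict(s.meta))


def savgol_derivative(
    s: SpectraSet, deriv: int, window: int = 17, polyorder: int = 2
) -> SpectraSet:
    """Savitzky-Golay derivative per cm^-1 with edge truncation; the grid is
    trimmed by half a window on each side."""
    est = SavitzkyGolayDerivative(deriv, window, polyorder, delta=s.spacing)
    values = est.fit_transform(s.absorbance)
    half = (window - 1) // 2
    return SpectraSet(
        s.grid[half:-half], values, list(s.sample_ids), dict(s.meta)
    )


@dataclass(eq=False)
class FittedPretreatment:
    """A recipe plus any training-derived statistics, reusable on new spectra.

    ``column_means``/``column_sds`` are populated only for autoscaling (on the
    retained grid); the sample-local recipes carry no statistics.
    """

    spec: PretreatmentSpec
    input_grid: np.ndarray
    retained_grid: np.ndarray
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    def transform(self, s: SpectraSet) -> SpectraSet:
        """Apply the full chain to new spectra measured on the training grid."""
        if s.grid.size != self.input_grid.size or not np.allclose(
            s.grid, self.input_grid, rtol=0, atol=1e-9
        ):
            raise ValidationError("grid does not match the fitted pre-treatment")
        out = s
        if self.spec.uses_snv:
            out = snv_transform(out)
        if self.spec.deriv_order:
            out = savgol_derivative(
                out, self.spec.deriv_order, self.spec.sg_window, self.spec.sg_polyorder
            )
        if self.column_means is not None:
            scaler = Autoscaler()
            scaler.mean_ = self.column_means
            scaler.scale_ = self.column_sds
            out = SpectraSet(
                out.grid,
                scaler.transform(out.absorbance),
                list(out.sample_ids),
                dict(out.meta),
            )
        return out


def autoscale_fit(train: SpectraSet) -> FittedPretreatment:
    """Fit per-channel mean/SD (n-1) on the training set."""
    scaler = Autoscaler().fit(train.absorbance)
    return FittedPretreatment(
        PretreatmentSpec("autoscale"), train.grid, train.grid,
        scaler.mean_, scaler.scale_,
    )


def autoscale_apply(f: FittedPretreatment, s: SpectraSet) -> SpectraSet:
    """Apply stored autoscaling statistics; zero-SD channels map to 0."""
    return f.transform(s)


def fit_pretreatment(spec: PretreatmentSpec, train: SpectraSet) -> FittedPretreatment:
    """Fit a recipe on the training set only.

    The sample-local steps need no statistics; for ``autoscale`` the channel
    means/SDs come from the (already sample-locally processed, here: raw)
    training spectra.
    """
    out = train
    if spec.uses_snv:
        out = snv_transform(out)
    if spec.deriv_order:
        out = savgol_derivative(out, spec.deriv_order, spec.sg_window, spec.sg_polyorder)
    means = sds = None
    if spec.uses_autoscale:
        scaler = Autoscaler().fit(out.absorbance)
        means, sds = scaler.mean_, scaler.scale_
    return FittedPretreatment(spec, train.grid, out.grid, means, sds)


def apply_pretreatment(
    spec: PretreatmentSpec, train: SpectraSet, others: list[SpectraSet] = ()
) -> tuple[SpectraSet, list[SpectraSet], FittedPretreatment]:
    """Pre-treat a training set and any further sets with strict separation.

    Sample-local steps (SNV, derivatives, in that order for the combined
    recipes) are applied identically everywhere; the statistics-bearing step
    (autoscaling) is fitted on ``train`` only and applied to all sets.
    """
    fitted = fit_pretreatment(spec, train)
    return fitted.transform(train), [fitted.transform(o) for o in others], fitted
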