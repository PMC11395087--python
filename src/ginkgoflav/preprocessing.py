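"""Spectral pretreatments: MSC, SNV and Savitzky-Golay smoothing.

Multiplicative scatter correction (MSC) regresses each spectrum on a
reference mean spectrum and removes the fitted offset and gain,
``(x_i - b_i) / k_i``.  Standard normal variate (SNV) centers and scales
each spectrum to unit standard deviation (n−1 denominator).  The
Savitzky-Golay filter replaces each band with the center value of a local
least-squares polynomial fit, realized as a fixed convolution in the
interior with polynomial extrapolation in the two edge half-windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

VALID_METHODS = ("raw", "msc", "snv", "savgol")


@dataclass(frozen=True)
class PreprocessConfig:
    method: str = "raw"
    savgol_half_window: int = 5   # window length 2m+1
    savgol_poly_order: int = 2

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of "
                f"{VALID_METHODS}")
        m = self.savgol_half_window
        if m < 1:
            raise ValueError("savgol_half_window must be >= 1")
        if 2 * m + 1 <= self.savgol_poly_order:
            raise ValueError("window 2m+1 must exceed the polynomial order")


@dataclass
class MSCModel:
    """Reference mean spectrum and per-sample affine fits against it."""

    reference_mean: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray


def _msc_regress(X: np.ndarray, reference: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-row univariate least squares of x_i on the reference spectrum."""
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 1e-300:
        raise ValueError("reference mean spectrum has zero variance")
    slopes = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    intercepts = X.mean(axis=1) - slopes * ref.mean()
    return slopes, intercepts


def msc_fit(spectra: np.ndarray) -> MSCModel:
    """Fit MSC on a matrix: reference = columnwise mean, then per-sample
    slope/intercept from regressing each row on the reference."""
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("MSC needs a 2-D matrix with at least 2 spectra")
    reference = X.mean(axis=0)
    slopes, intercepts = _msc_regress(X, reference)
    return MSCModel(reference_mean=reference, slopes=slopes,
                    intercepts=intercepts)


def msc_transform(spectra: np.ndarray, model: MSCModel) -> np.ndarray:
    """Scatter-correct rows against the model's reference:
    regress each row on the reference and return ``(x_i - b_i) / k_i``."""
    X = np.asarray(spectra, dtype=float)
    if X.shape[1] != model.reference_mean.shape[0]:
        raise ValueError("band count does not match the fitted MSC model")
    slopes, intercepts = _msc_regress(X, model.reference_mean)
    tiny = np.abs(slopes) < 1e-12
    if tiny.any():
        raise ValueError(
            f"near-zero MSC slope for sample rows {np.flatnonzero(tiny).tolist()}")
    return (X - intercepts[:, None]) / slopes[:, None]


def snv(spectra: np.ndarray) -> np.ndarray:
    """Row-wise standard normal variate: center and scale to unit sd
    (n−1 denominator)."""
    X = np.asarray(spectra, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    sd = X.std(axis=1, ddof=1)
    bad = ~(sd > 0)
    if bad.any():
        raise ValueError(
            f"constant spectrum rows {np.flatnonzero(bad).tolist()}: "
            "SNV undefined")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def savgol(spectra: np.ndarray, half_window: int = 5,
           poly_order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing along bands (window 2m+1).

    Edge bands use the polynomial fitted to the terminal window
    (``mode='interp'``) so that any signal of degree <= poly_order passes
    through unchanged over the whole spectrum, not just the interior.
    """
    X = np.asarray(spectra, dtype=float)
    window = 2 * int(half_window) + 1
    if window <= poly_order:
        raise ValueError("window 2m+1 must exceed the polynomial order")
    if window > X.shape[-1]:
        raise ValueError(
            f"window {window} exceeds band count {X.shape[-1]}")
    return savgol_filter(X, window_length=window, polyorder=poly_order,
                         axis=-1, mode="interp")


def apply_preprocessing(spectra: np.ndarray,
                        config: PreprocessConfig) -> np.ndarray:
    """Dispatch to the configured pretreatment.

    ``msc`` fits its reference on the provided matrix; for split-safe
    train/test use, fit a :class:`FittedPreprocessor` on the training rows
    instead.
    """
    X = np.asarray(spectra, dtype=float)
    if config.method == "raw":
        return X.copy()
    if config.method == "snv":
        return snv(X)
    if config.method == "savgol":
        return savgol(X, config.savgol_half_window, config.savgol_poly_order)
    return msc_transform(X, msc_fit(X))


class FittedPreprocessor:
    """Split-safe pretreatment: state (the MSC reference) is learned from
    the training rows only and reused on the test rows.  SNV and SavGol are
    per-row and stateless."""

    def __init__(self, config: PreprocessConfig):
        self.config = config
        self._msc_model: MSCModel | None = None

    def fit(self, X: np.ndarray) -> "FittedPreprocessor":
        if self.config.method == "msc":
            self._msc_model = msc_fit(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        cfg = self.config
        if cfg.method == "msc":
            if self._msc_model is None:
                raise RuntimeError("MSC preprocessor used before fit()")
            return msc_transform(X, self._msc_model)
        return apply_preprocessing(X, cfg)
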