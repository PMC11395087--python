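"""Leaf segmentation and per-sample mean-spectrum extraction.

A visible-light RGB rendering is taken from three cube bands; the leaf mask
is the intersection of two Otsu segmentations — the grayscale foreground
(leaf brighter than the dark cloth) and the excess-green region
(EGI = 2G − R − B, high for vegetation) — cleaned to its largest connected
component.  Masked pixels are then averaged per band to give one spectrum
per sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_RGB_WAVELENGTHS = (670.0, 550.0, 450.0)
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


class NoContrastError(ValueError):
    """Otsu thresholding was asked for a (near-)constant image."""


class EmptyMaskError(ValueError):
    """The gray/EGI mask intersection contains no pixels."""


class TooFewPixelsError(ValueError):
    """The leaf mask has fewer pixels than the configured minimum."""


def extract_visible_rgb(
    cube: np.ndarray,
    wavelengths: np.ndarray,
    rgb_wavelengths: tuple[float, float, float] = DEFAULT_RGB_WAVELENGTHS,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Slice the cube at the nearest bands to the requested R, G, B
    wavelengths.  Returns ``(rgb, actual_wavelengths)`` with rgb shaped
    height x width x 3."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    lo, hi = wavelengths.min(), wavelengths.max()
    channels, actual = [], []
    for req in rgb_wavelengths:
        if not lo <= req <= hi:
            raise ValueError(
                f"requested wavelength {req} nm outside grid range "
                f"[{lo}, {hi}] nm")
        idx = int(np.argmin(np.abs(wavelengths - req)))
        channels.append(cube[:, :, idx])
        actual.append(float(wavelengths[idx]))
    return np.stack(channels, axis=-1), tuple(actual)


def to_grayscale(
    rgb: np.ndarray,
    weights: tuple[float, float, float] = LUMINANCE_WEIGHTS,
) -> np.ndarray:
    """Weighted luminance sum of the R, G, B channels."""
    rgb = np.asarray(rgb, dtype=float)
    w = np.asarray(weights, dtype=float)
    return rgb @ w


def compute_egi(rgb: np.ndarray) -> np.ndarray:
    """Excess-green index 2G − R − B, high over green vegetation."""
    rgb = np.asarray(rgb, dtype=float)
    return 2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    The histogram uses ``n_bins`` uniform bins over [min, max]; ties are
    broken toward the lowest qualifying bin edge.  Returns the bin edge
    separating the two classes; the foreground is ``image >= threshold``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = np.asarray(image, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise NoContrastError("image has no finite pixels")
    vmin, vmax = vals.min(), vals.max()
    if vmax <= vmin:
        raise NoContrastError("image is constant; no threshold exists")
    hist, edges = np.histogram(vals, bins=n_bins, range=(vmin, vmax))
    return _otsu_from_histogram(hist, edges)


def _otsu_from_histogram(hist: np.ndarray, edges: np.ndarray) -> float:
    """Between-class-variance maximization over all bin splits."""
    hist = np.asarray(hist, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    w0 = np.cumsum(hist)                    # mass in bins [0..t]
    m0 = np.cumsum(hist * centers)
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = sigma_b[:-1]                  # split after bin t, t < n_bins-1
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    if not valid.any():
        raise NoContrastError("all mass falls in a single histogram bin")
    sigma_b = np.where(valid, sigma_b, -np.inf)
    best = sigma_b.max()
    # splits across empty histogram bins tie exactly in real arithmetic;
    # compare with a relative tolerance so float noise cannot scramble the
    # lowest-edge tie-break
    tol = 1e-10 * abs(best)
    t = int(np.argmax(sigma_b >= best - tol))
    return float(edges[t + 1])


def leaf_mask(
    gray: np.ndarray,
    egi: np.ndarray,
    n_bins: int = 256,
    *,
    gray_polarity: str = "foreground",
    sample_id: str | None = None,
) -> tuple[np.ndarray, dict]:
    """Intersect the grayscale-Otsu and EGI-Otsu foregrounds, keep the
    largest connected component.

    ``gray_polarity='background'`` gives the literal reading in which the
    gray mask selects the dark-cloth region; intersecting that with the
    green region is normally empty and exists only for exploration.

    Returns ``(mask, qc)`` where qc records both thresholds and the final
    pixel count.
    """
    gray = np.asarray(gray, dtype=float)
    egi = np.asarray(egi, dtype=float)
    if gray.shape != egi.shape:
        raise ValueError("gray and EGI images must share the spatial grid")
    gray_t = otsu_threshold(gray, n_bins)
    egi_t = otsu_threshold(egi, n_bins)
    gray_mask = gray < gray_t if gray_polarity == "background" \
        else gray >= gray_t
    mask = gray_mask & (egi >= egi_t)
    label = f" for sample {sample_id}" if sample_id else ""
    if not mask.any():
        raise EmptyMaskError(f"gray/EGI mask intersection is empty{label}")
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    qc = {
        "gray_threshold": float(gray_t),
        "egi_threshold": float(egi_t),
        "pixel_count": int(mask.sum()),
    }
    return mask, qc


def mean_spectrum(
    cube: np.ndarray,
    mask: np.ndarray,
    *,
    min_leaf_pixels: int = 50,
    sample_id: str | None = None,
) -> tuple[np.ndarray, int]:
    """Per-band mean reflectance over masked pixels (NaN pixels excluded
    band-wise).  Returns ``(spectrum, n_pixels)``."""
    mask = np.asarray(mask, dtype=bool)
    n_pixels = int(mask.sum())
    label = f" for sample {sample_id}" if sample_id else ""
    if n_pixels < min_leaf_pixels:
        raise TooFewPixelsError(
            f"leaf mask has {n_pixels} pixels (< {min_leaf_pixels}){label}")
    pixels = np.asarray(cube, dtype=float)[mask]
    with np.errstate(invalid="ignore"):
        spectrum = np.nanmean(pixels, axis=0)
    return spectrum, n_pixels


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def band_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a spectra table that are band reflectances (named by
    wavelength)."""
    cols = []
    for c in table.columns:
        try:
            float(c)
        except (TypeError, ValueError):
            continue
        cols.append(c)
    return cols


def build_spectra_table(
    spectra: list[tuple[str, np.ndarray, int]],
    tfc_table: pd.DataFrame,
    wavelengths: np.ndarray,
) -> pd.DataFrame:
    """Join per-sample mean spectra to the TFC table.

    ``spectra`` holds ``(sample_id, spectrum, n_pixels)``; ``tfc_table``
    must contain sample_id, phenotype and a TFC column (``tfc`` or
    ``true_tfc``).  Output row order follows ``tfc_table``; band columns are
    named by wavelength.
    """
    by_id: dict[str, np.ndarray] = {}
    dup = []
    for sid, spec, _ in spectra:
        if sid in by_id:
            dup.append(sid)
        by_id[sid] = np.asarray(spec, dtype=float)
    table_ids = list(tfc_table["sample_id"])
    dup += [sid for sid, n in
            tfc_table["sample_id"].value_counts().items() if n > 1]
    missing = [sid for sid in by_id if sid not in set(table_ids)]
    missing += [sid for sid in table_ids if sid not in by_id]
    if dup or missing:
        raise ValueError(
            f"spectra/TFC join failed; duplicated ids: {sorted(set(dup))}, "
            f"unmatched ids: {sorted(set(missing))}")
    tfc_col = "tfc" if "tfc" in tfc_table.columns else "true_tfc"
    mat = np.vstack([by_id[sid] for sid in table_ids])
    out = pd.DataFrame({
        "sample_id": table_ids,
        "phenotype": list(tfc_table["phenotype"]),
        "tfc": list(tfc_table[tfc_col]),
    })
    bands = pd.DataFrame(mat, columns=[f"{w:.4f}" for w in
                                       np.asarray(wavelengths, dtype=float)])
    return pd.concat([out, bands], axis=1)
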