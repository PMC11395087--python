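"""Raw-intensity to reflectance conversion with white/dark references.

Reflectance is the elementwise ratio ``(raw - dark) / (white - dark)``:
the dark frame removes the sensor's dark current and the white frame (a
standard whiteboard at ~100% reflectance) normalizes the illumination and
spectral response.  Output is intentionally not clipped to [0, 1] — sensor
noise can push values slightly out of range, and clipping would bias the
scatter-correction steps downstream.
"""

from __future__ import annotations

import numpy as np


class DegenerateReferenceError(ValueError):
    """white − dark fell below epsilon at one or more pixels."""


def calibrate_cube(
    raw: np.ndarray,
    white: np.ndarray,
    dark: np.ndarray,
    *,
    epsilon: float = 1e-6,
    mask_degenerate: bool = False,
) -> np.ndarray:
    """Convert a raw cube (height x width x bands) to reflectance.

    ``white`` and ``dark`` may be full frames matching ``raw``'s shape, or
    1-D per-band vectors (spatially averaged references).  Pixels where
    ``white - dark < epsilon`` raise :class:`DegenerateReferenceError`
    unless ``mask_degenerate`` is set, in which case they become NaN and are
    excluded from later per-band means.
    """
    raw = np.asarray(raw, dtype=float)
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    for name, ref in (("white", white), ("dark", dark)):
        if ref.ndim == 1:
            if ref.shape[0] != raw.shape[-1]:
                raise ValueError(
                    f"{name} reference has {ref.shape[0]} bands, "
                    f"cube has {raw.shape[-1]}")
        elif ref.shape != raw.shape:
            raise ValueError(
                f"{name} reference shape {ref.shape} does not match "
                f"cube shape {raw.shape}")
    denom = white - dark
    degenerate = denom < epsilon
    n_bad = int(np.count_nonzero(degenerate))
    if n_bad and not mask_degenerate:
        raise DegenerateReferenceError(
            f"white - dark < {epsilon} at {n_bad} pixel/band entries")
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw - dark) / denom
    if n_bad:
        refl = np.where(np.broadcast_to(degenerate, refl.shape), np.nan, refl)
    return refl
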