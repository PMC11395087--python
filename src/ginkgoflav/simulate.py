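"""Synthetic hyperspectral leaf scenes with known ground truth.

The generator emulates the statistical structure of a line-scan hyperspectral
survey of *Ginkgo biloba* leaves on a dark cloth background: per-sample total
flavonoid content (TFC, mg·g⁻¹) drawn from a truncated normal with a lobed
(LL) vs unlobed (UL) phenotype contrast, vegetation-like reflectance spectra
with a chlorophyll plateau, a red edge near 680–750 nm and weak water
features above 750 nm, fan-shaped leaf masks (with marginal clefts for the
lobed phenotype), and raw-intensity cubes rendered through the inverse of
the white/dark reference calibration with additive Gaussian sensor noise.

The recoverable signal is explicit: the mean reflectance over a configurable
band window (default 560–620 nm) is an affine function of true TFC, so a
regression pipeline that works must recover the configured gain.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.stats import truncnorm

from . import envi

__all__ = [
    "SimulationConfig",
    "Scene",
    "make_wavelength_grid",
    "sample_tfc_values",
    "leaf_reflectance_spectrum",
    "background_spectrum",
    "render_leaf_mask",
    "render_raw_scene",
    "simulate_spectra_table",
    "dataset_truth",
    "iter_scenes",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the emulated survey: 407 sample groups (207 lobed,
    200 unlobed), TFC in [6.1969, 20.5526] mg·g⁻¹ with the bulk of mass at
    12–15 mg·g⁻¹ and a higher lobed-group mean, spectra over
    381.8–1020.5 nm.
    """

    n_lobed: int = 207
    n_unlobed: int = 200
    image_height: int = 64
    image_width: int = 64
    n_bands: int = 100
    wavelength_start: float = 381.8
    wavelength_end: float = 1020.5
    tfc_min: float = 6.1969
    tfc_max: float = 20.5526
    tfc_mode_low: float = 12.0
    tfc_mode_high: float = 15.0
    tfc_mean: float = 13.5
    tfc_sd: float = 2.5
    lobed_tfc_shift: float = 1.5
    sensor_noise_sd: float = 0.005
    n_gross_outliers: int = 20
    outlier_shift_sd_multiple: float = 10.0
    # spectral-TFC link (flavonoid absorbance proxy window)
    signal_window: tuple[float, float] = (560.0, 620.0)
    signal_gain: float = -0.004
    signal_intercept: float = 0.16
    # optional per-sample multiplicative/additive scatter (off by default)
    scatter_gain_sd: float = 0.0
    scatter_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lobed, self.n_unlobed, self.image_height,
               self.image_width, self.n_bands) <= 0:
            raise ValueError("counts and dimensions must be positive")
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image dimensions must be at least 16 pixels")
        if not self.wavelength_start < self.wavelength_end:
            raise ValueError("wavelength_start must be < wavelength_end")
        if not (self.tfc_min < self.tfc_mode_low <= self.tfc_mode_high
                < self.tfc_max):
            raise ValueError(
                "require tfc_min < tfc_mode_low <= tfc_mode_high < tfc_max")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")
        if self.n_gross_outliers < 0:
            raise ValueError("n_gross_outliers must be >= 0")
        if self.n_gross_outliers > self.n_lobed + self.n_unlobed:
            raise ValueError("cannot inject more outliers than samples")

    @property
    def n_samples(self) -> int:
        return self.n_lobed + self.n_unlobed

    @property
    def wavelengths(self) -> np.ndarray:
        return make_wavelength_grid(
            self.n_bands, self.wavelength_start, self.wavelength_end)


@dataclass
class Scene:
    """One rendered sample: raw cube plus its reference frames and truth."""

    sample_id: str
    raw: np.ndarray          # height x width x bands, raw intensity
    white: np.ndarray        # height x width x bands
    dark: np.ndarray         # height x width x bands
    true_mask: np.ndarray    # height x width bool
    wavelengths: np.ndarray  # bands


def make_wavelength_grid(n_bands: int, start: float, end: float) -> np.ndarray:
    """Evenly spaced band-center wavelengths from ``start`` to ``end`` (nm)."""
    if n_bands < 2:
        raise ValueError(f"need at least 2 bands, got {n_bands}")
    if not start < end:
        raise ValueError("start must be < end")
    return np.linspace(float(start), float(end), int(n_bands))


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal mean equals target."""

    def truncated_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd)

    # truncated mean is strictly increasing in loc and bracketed by [lo, hi]
    return optimize.brentq(
        lambda loc: truncated_mean(loc) - target_mean, lo, hi, xtol=1e-10)


def sample_tfc_values(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, float]]:
    """Draw ``(phenotype, true_tfc)`` pairs, LL block first.

    Each phenotype is a truncated normal on [tfc_min, tfc_max]; the location
    parameters are solved so the truncated group means are exactly
    ``tfc_mean`` (UL) and ``tfc_mean + lobed_tfc_shift`` (LL), making the
    expected group-mean difference equal the configured shift.
    """
    lo, hi, sd = config.tfc_min, config.tfc_max, config.tfc_sd
    out: list[tuple[str, float]] = []
    for phen, n, target in (
        ("LL", config.n_lobed, config.tfc_mean + config.lobed_tfc_shift),
        ("UL", config.n_unlobed, config.tfc_mean),
    ):
        if not lo < target < hi:
            raise ValueError(f"target mean {target} outside [{lo}, {hi}]")
        loc = _truncnorm_loc(target, sd, lo, hi)
        a, b = (lo - loc) / sd, (hi - loc) / sd
        vals = truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)
        out.extend((phen, float(v)) for v in vals)
    return out


def _signal_weights(config: SimulationConfig,
                    wavelengths: np.ndarray) -> np.ndarray:
    """Band weights of the TFC-linked component, normalized so the mean over
    in-window bands is exactly 1 (the window-mean amplitude is then affine in
    TFC with slope ``signal_gain``)."""
    lo, hi = config.signal_window
    center, width = 0.5 * (lo + hi), (hi - lo) / 3.33
    w = np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    in_window = (wavelengths >= lo) & (wavelengths <= hi)
    if not in_window.any():
        raise ValueError(
            f"no band falls inside the signal window {config.signal_window}")
    return w / w[in_window].mean()


def _base_leaf_curve(wavelengths: np.ndarray) -> np.ndarray:
    """TFC-independent green-vegetation reflectance shape."""
    wl = wavelengths
    red_edge = 0.35 / (1.0 + np.exp(-(wl - 715.0) / 12.0))
    return (
        0.05
        + 0.10 * np.exp(-0.5 * ((wl - 550.0) / 40.0) ** 2)   # green peak
        - 0.02 * np.exp(-0.5 * ((wl - 670.0) / 15.0) ** 2)   # chlorophyll dip
        + red_edge                                            # red edge → NIR
        - 0.02 * np.exp(-0.5 * ((wl - 900.0) / 20.0) ** 2)   # weak O-H feature
        - 0.04 * np.exp(-0.5 * ((wl - 970.0) / 25.0) ** 2)   # water band
    )


def leaf_reflectance_spectrum(
    true_tfc: float,
    wavelengths: np.ndarray,
    rng: np.random.Generator | None = None,
    *,
    noise_sd: float = 0.0,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Leaf endmember reflectance for one sample.

    The spectrum is the base vegetation curve plus an amplitude
    ``signal_intercept + signal_gain * true_tfc`` times the normalized
    window weights, plus optional zero-mean Gaussian band noise.
    """
    if true_tfc <= 0:
        raise ValueError("true_tfc must be positive")
    cfg = config if config is not None else SimulationConfig()
    wavelengths = np.asarray(wavelengths, dtype=float)
    amp = cfg.signal_intercept + cfg.signal_gain * float(true_tfc)
    spectrum = _base_leaf_curve(wavelengths) + amp * _signal_weights(
        cfg, wavelengths)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        spectrum = spectrum + rng.normal(0.0, noise_sd, spectrum.shape)
    return np.clip(spectrum, 1e-4, 1.0 - 1e-4)


def background_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Dark-cloth background: flat, low, slightly sloped reflectance."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.04 + 1e-5 * (wl - wl[0])


def render_leaf_mask(
    height: int,
    width: int,
    lobed: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fan-shaped leaf silhouette; lobed leaves get 1-3 marginal clefts.

    Returns a boolean image with a single connected foreground component
    covering 10-60% of the pixels.
    """
    if height < 16 or width < 16:
        raise ValueError("mask dimensions must be at least 16 pixels")
    cy, cx = 0.88 * height, 0.5 * width
    yy, xx = np.mgrid[0:height, 0:width]
    dy, dx = cy - yy, xx - cx          # fan opens upward from near the bottom
    r = np.hypot(dy, dx)
    theta = np.arctan2(dx, dy)         # 0 == straight up

    span = rng.uniform(1.5, 2.0)
    target_frac = rng.uniform(0.22, 0.42)
    rmax = np.sqrt(2.0 * target_frac * height * width / span)
    rmax = min(rmax, 0.95 * cy, 0.98 * (width / 2) / max(np.sin(span / 2), 1e-6))
    freq = rng.integers(2, 5)
    phase = rng.uniform(0, 2 * np.pi)
    edge = rmax * (1.0 + 0.05 * np.sin(freq * theta + phase))
    mask = (np.abs(theta) <= span / 2) & (r <= edge)

    if lobed:
        n_clefts = int(rng.integers(1, 4))
        for _ in range(n_clefts):
            tc = rng.uniform(-0.8, 0.8) * span / 2
            half_width = rng.uniform(0.04, 0.08)
            depth = rng.uniform(0.40, 0.55)  # cleft reaches down to depth*rmax
            mask &= ~((np.abs(theta - tc) < half_width) & (r > depth * rmax))

    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        raise RuntimeError("degenerate leaf mask: no foreground")
    if n_comp > 1:  # keep the largest piece (clefts cannot normally split it)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    frac = mask.mean()
    if not 0.10 <= frac <= 0.60:
        raise RuntimeError(f"leaf coverage {frac:.3f} outside [0.10, 0.60]")
    return mask


def _reference_frames(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """White / dark reference frames (height x width x bands).

    The white frame sits near full scale (whiteboard at ~100% reflectance)
    with a mild lamp band profile and ~1% smooth spatial non-uniformity; the
    dark frame is a small offset, so white − dark ≈ 1.
    """
    h, w, b = config.image_height, config.image_width, config.n_bands
    t = np.linspace(0.0, 1.0, b)
    lamp = 0.98 + 0.05 * np.sin(np.pi * t)
    yy, xx = np.mgrid[0:h, 0:w]
    ripple = np.sin(2 * np.pi * yy / h + rng.uniform(0, 2 * np.pi)) * \
        np.cos(2 * np.pi * xx / w + rng.uniform(0, 2 * np.pi))
    white = lamp[None, None, :] * (1.0 + 0.01 * ripple[:, :, None])
    dark = 0.02 * (1.0 + 0.05 * ripple[:, :, None]) * np.ones((1, 1, b))
    dark = np.broadcast_to(dark, (h, w, b)).copy()
    return white, dark


def render_raw_scene(
    mask: np.ndarray,
    leaf_spectrum: np.ndarray,
    bg_spectrum: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render raw intensity from assigned reflectance: the inverse of the
    white/dark calibration, ``raw = R*(white-dark) + dark + noise``.

    Returns ``(raw, white, dark)``.
    """
    mask = np.asarray(mask, dtype=bool)
    leaf = np.asarray(leaf_spectrum, dtype=float)
    bg = np.asarray(bg_spectrum, dtype=float)
    wl = config.wavelengths
    visible = (wl >= 400.0) & (wl <= 700.0)
    if visible.any() and bg[visible].mean() >= leaf[visible].mean():
        raise ValueError("background must be darker than the leaf in the "
                         "visible bands (dark cloth assumption)")
    white, dark = _reference_frames(config, rng)
    if not np.all(white > dark):
        raise ValueError("white reference must exceed dark everywhere")
    refl = np.where(mask[:, :, None], leaf[None, None, :], bg[None, None, :])
    raw = refl * (white - dark) + dark
    if config.sensor_noise_sd > 0:
        raw = raw + rng.normal(0.0, config.sensor_noise_sd, raw.shape)
    return raw, white, dark


@dataclass
class _SamplePlan:
    truth: pd.DataFrame
    leaf_spectra: np.ndarray            # n_samples x bands (post-injection)
    scene_seeds: list[np.random.SeedSequence]


def _plan(config: SimulationConfig) -> _SamplePlan:
    master = np.random.SeedSequence(config.seed)
    tfc_ss, spec_ss, scene_ss, out_ss = master.spawn(4)
    rng = np.random.default_rng(tfc_ss)
    pairs = sample_tfc_values(config, rng)
    n = len(pairs)
    ids = [f"{phen}_{i + 1:04d}" for i, (phen, _) in enumerate(pairs)]
    wl = config.wavelengths

    spec_seeds = spec_ss.spawn(n)
    spectra = np.empty((n, config.n_bands))
    for i, (ss, (_, tfc)) in enumerate(zip(spec_seeds, pairs)):
        srng = np.random.default_rng(ss)
        spectra[i] = leaf_reflectance_spectrum(
            tfc, wl, srng, noise_sd=config.sensor_noise_sd, config=config)
        if config.scatter_gain_sd > 0 or config.scatter_offset_sd > 0:
            gain = 1.0 + srng.normal(0.0, config.scatter_gain_sd)
            offset = srng.normal(0.0, config.scatter_offset_sd)
            spectra[i] = np.clip(gain * spectra[i] + offset, 1e-4, 1 - 1e-4)

    flags = np.zeros(n, dtype=bool)
    if config.n_gross_outliers > 0:
        orng = np.random.default_rng(out_ss)
        band_sd = spectra.std(axis=0, ddof=1)
        chosen = orng.choice(n, size=config.n_gross_outliers, replace=False)
        # per-band magnitude is multiple x band-sd; the sign is independent
        # per sample and band so injected outliers do not share a direction
        # (a shared direction would mask itself in a non-robust T² screen)
        signs = orng.choice([-1.0, 1.0],
                            size=(config.n_gross_outliers, config.n_bands))
        spectra[chosen] = np.clip(
            spectra[chosen]
            + config.outlier_shift_sd_multiple * band_sd[None, :] * signs,
            1e-4, 1 - 1e-4)
        flags[chosen] = True

    truth = pd.DataFrame({
        "sample_id": ids,
        "phenotype": [p for p, _ in pairs],
        "true_tfc": [t for _, t in pairs],
        "is_injected_outlier": flags,
    })
    return _SamplePlan(truth=truth, leaf_spectra=spectra,
                       scene_seeds=scene_ss.spawn(n))


def dataset_truth(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth table (sample_id, phenotype, true_tfc,
    is_injected_outlier) for the configured dataset."""
    return _plan(config).truth


def simulate_spectra_table(config: SimulationConfig) -> pd.DataFrame:
    """Per-sample leaf endmember spectra joined to the truth table.

    Bypasses image rendering/segmentation: columns are sample_id, phenotype,
    tfc, is_injected_outlier, then one column per band named by wavelength.
    """
    plan = _plan(config)
    wl = config.wavelengths
    spec = pd.DataFrame(plan.leaf_spectra,
                        columns=[f"{w:.4f}" for w in wl])
    truth = plan.truth.rename(columns={"true_tfc": "tfc"})
    return pd.concat([truth.reset_index(drop=True), spec], axis=1)


def iter_scenes(config: SimulationConfig) -> Iterator[Scene]:
    """Yield one rendered :class:`Scene` per sample (constant memory)."""
    plan = _plan(config)
    wl = config.wavelengths
    bg = background_spectrum(wl)
    for i, row in enumerate(plan.truth.itertuples(index=False)):
        srng = np.random.default_rng(plan.scene_seeds[i])
        mask = render_leaf_mask(config.image_height, config.image_width,
                                row.phenotype == "LL", srng)
        raw, white, dark = render_raw_scene(
            mask, plan.leaf_spectra[i], bg, config, srng)
        yield Scene(sample_id=row.sample_id, raw=raw, white=white, dark=dark,
                    true_mask=mask, wavelengths=wl)


def truth_csv_bytes(truth: pd.DataFrame) -> bytes:
    """Canonical CSV serialization of a truth table (deterministic bytes)."""
    buf = io.StringIO()
    truth.to_csv(buf, index=False, float_format="%.10f")
    return buf.getvalue().encode()


def generate_dataset(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[Scene], pd.DataFrame]:
    """Materialize every scene plus the ground-truth table.

    With ``out_dir`` set, each scene is written as ENVI cubes
    (``<id>.img/.hdr`` plus ``<id>_white`` / ``<id>_dark``) and the truth
    table as ``truth.csv``.  Note the full default dataset occupies ~2 GB in
    memory; prefer :func:`iter_scenes` for streaming runs.
    """
    truth = dataset_truth(config)
    scenes: list[Scene] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out}: {exc}") from exc
    for scene in iter_scenes(config):
        scenes.append(scene)
        if out is not None:
            try:
                envi.write_envi(out / scene.sample_id, scene.raw,
                                scene.wavelengths)
                envi.write_envi(out / f"{scene.sample_id}_white", scene.white,
                                scene.wavelengths)
                envi.write_envi(out / f"{scene.sample_id}_dark", scene.dark,
                                scene.wavelengths)
            except OSError as exc:
                raise OSError(
                    f"failed writing scene {scene.sample_id} under {out}: {exc}"
                ) from exc
    if out is not None:
        (out / "truth.csv").write_bytes(truth_csv_bytes(truth))
    return scenes, truth
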