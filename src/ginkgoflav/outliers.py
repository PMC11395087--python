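"""Hotelling T² spectral outlier screening in principal-component space.

Spectra are column-centered and projected onto the smallest number of
principal components reaching a cumulative-variance target (default 95%).
Each sample's T² is the squared Mahalanobis distance in score space,
T²_i = Σ_j t_ij² / λ_j, compared against the F-distribution control limit

    T²_lim = p (n−1)(n+1) / (n (n−p)) · F(1−α; p, n−p).

Samples above the limit are flagged and dropped before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.decomposition import PCA


class DegenerateSpectraError(ValueError):
    """The spectra matrix has (numerically) zero variance."""


@dataclass
class OutlierResult:
    t2_scores: np.ndarray
    threshold: float
    flagged_ids: list[str]
    n_components: int
    variance_explained: float
    alpha: float
    sample_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "n_components": int(self.n_components),
            "variance_explained": float(self.variance_explained),
            "alpha": float(self.alpha),
            "flagged": [
                {"sample_id": sid,
                 "t2": float(self.t2_scores[self.sample_ids.index(sid)])}
                for sid in self.flagged_ids
            ],
            "n_flagged": len(self.flagged_ids),
        }


def hotelling_t2_screen(
    spectra: np.ndarray,
    *,
    variance_target: float = 0.95,
    alpha: float = 0.05,
    sample_ids: list[str] | None = None,
) -> OutlierResult:
    """Screen rows of ``spectra`` (samples x bands) for T² outliers."""
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2:
        raise ValueError("spectra must be a samples x bands matrix")
    n, k = X.shape
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if len(sample_ids) != n:
        raise ValueError("sample_ids length does not match row count")
    Xc = X - X.mean(axis=0)
    total_var = float(np.var(Xc, axis=0, ddof=1).sum())
    if not np.isfinite(total_var) or total_var <= 1e-24:
        raise DegenerateSpectraError(
            "spectra have zero total variance; T² screening is undefined")
    max_p = min(n - 2, k)
    if max_p < 1:
        raise ValueError("need n > p + 1 samples to screen")
    pca = PCA(n_components=min(n - 1, k), svd_solver="full")
    scores = pca.fit_transform(Xc)
    cum = np.cumsum(pca.explained_variance_ratio_)
    p = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    p = min(p, max_p)
    lam = pca.explained_variance_[:p]
    if np.any(lam <= 1e-18):
        raise DegenerateSpectraError(
            "rank-deficient score covariance in the retained components")
    t2 = np.sum(scores[:, :p] ** 2 / lam[None, :], axis=1)
    threshold = (p * (n - 1) * (n + 1)) / (n * (n - p)) * \
        f_dist.ppf(1.0 - alpha, p, n - p)
    flagged = [sid for sid, s in zip(sample_ids, t2) if s > threshold]
    return OutlierResult(
        t2_scores=t2,
        threshold=float(threshold),
        flagged_ids=flagged,
        n_components=p,
        variance_explained=float(cum[p - 1]),
        alpha=alpha,
        sample_ids=list(sample_ids),
    )


def remove_outliers(table: pd.DataFrame,
                    result: OutlierResult) -> pd.DataFrame:
    """Drop flagged rows from a spectra table (by ``sample_id``)."""
    ids = set(table["sample_id"])
    unknown = [sid for sid in result.flagged_ids if sid not in ids]
    if unknown:
        raise ValueError(f"flagged ids not present in table: {unknown}")
    keep = ~table["sample_id"].isin(result.flagged_ids)
    if not keep.any():
        raise ValueError("all samples flagged as outliers; nothing retained")
    return table.loc[keep].reset_index(drop=True)
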