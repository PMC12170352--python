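"""Ordination of the pooled element space and trajectory-shape metrics.

Two scalar summaries describe the overall shape of a record's trajectory in
multivariate element space:

* **explored area** — the area of the confidence ellipse (default level 0.95)
  of the record's scores on the first two principal axes of the pooled
  ordination: ``area = pi * q * sqrt(det(S))`` where S is the 2x2 sample
  covariance of the scores and q the chi-square quantile with 2 df (a
  multivariate-t variant is selectable).  It measures how much of the shared
  multivariate space the trajectory visits.
* **three-centroid length** — the summed Euclidean distance between the
  centroids of the record's three main zones (a CONISS cut at k = 3),
  computed in the full element space, not the 2-D ordination.  It measures
  how far apart the record's main compositional states lie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import FLOAT_FORMAT, TransformedRecord
from .zonation import Zonation


@dataclass
class OrdinationResult:
    """PCA of a (pooled) transformed matrix.

    scores: samples x axes (centered columns); loadings: axes x elements;
    variance_fractions: per-axis share of total variance, non-increasing and
    summing to 1 over all axes.  record_ids labels each score row.
    """

    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray
    elements: list[str]
    record_ids: list[str]

    def record_scores(self, record_id: str, n_axes: int = 2) -> np.ndarray:
        mask = np.array([r == record_id for r in self.record_ids])
        if not mask.any():
            raise KeyError(f"no scores for record {record_id!r}")
        return self.scores[mask, :n_axes]


def pca(
    X: np.ndarray,
    elements: list[str] | None = None,
    record_ids: list[str] | None = None,
) -> OrdinationResult:
    """Covariance-based PCA on centered (not re-scaled) transformed values.

    Uses an SVD of the centered matrix; a deterministic sign convention makes
    the largest-magnitude loading of each axis positive, so repeated runs and
    different BLAS backends agree on orientation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 3 samples and 2 elements")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("matrix has rank 0 (all samples identical)")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: per axis, the largest-|.| loading is positive
    for a in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U * s
    var = s**2
    fractions = var / var.sum()
    n = X.shape[0]
    return OrdinationResult(
        scores=scores,
        loadings=Vt,
        variance_fractions=fractions,
        elements=list(elements) if elements else [f"e{j}" for j in range(X.shape[1])],
        record_ids=list(record_ids) if record_ids else ["record"] * n,
    )


def explored_area(scores: np.ndarray, level: float = 0.95, kind: str = "norm") -> float:
    """Area of the confidence ellipse of 2-D ordination scores.

    ``kind="norm"`` (default) uses the normal-theory chi-square quantile
    ``q = chi2.ppf(level, 2)``; ``kind="t"`` uses the multivariate-t scaling
    ``q = 2 (n-1) / (n-2) * F.ppf(level, 2, n-2)`` — at fixed n the two differ
    by a scalar factor.  Collinear or fewer than 3 points have no ellipse
    (NaN).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("explored_area expects an (n, 2) score matrix")
    n = scores.shape[0]
    if n < 3:
        return float("nan")
    S = np.cov(scores, rowvar=False)
    det = float(np.linalg.det(S))
    if det <= 0 or not np.isfinite(det):
        return float("nan")
    if kind == "norm":
        q = stats.chi2.ppf(level, df=2)
    elif kind == "t":
        if n < 4:
            return float("nan")
        q = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)
    else:
        raise ValueError(f"unknown ellipse kind {kind!r}")
    return float(np.pi * q * np.sqrt(det))


def three_centroid_length(
    trec: TransformedRecord, zon: Zonation, mode: str = "chronological"
) -> float:
    """Summed Euclidean distance between the three zone centroids.

    Centroids are element-wise means of each zone's samples in the full
    multivariate space.  ``chronological`` sums d(c1,c2) + d(c2,c3) along the
    record's time order; ``all_pairs`` adds d(c1,c3).
    """
    if mode not in ("chronological", "all_pairs"):
        raise ValueError(f"unknown centroid length mode {mode!r}")
    if zon.k != 3 or zon.zone_labels is None:
        raise ValueError("three_centroid_length requires a zonation cut at k = 3")
    if zon.n_samples != trec.n_samples:
        raise ValueError("zonation and record are on different sample grids")
    centroids = []
    for z in (1, 2, 3):
        mask = zon.zone_labels == z
        if not mask.any():
            raise ValueError(f"zone {z} is empty")
        centroids.append(trec.values[mask].mean(axis=0))
    c1, c2, c3 = centroids
    length = float(np.linalg.norm(c2 - c1) + np.linalg.norm(c3 - c2))
    if mode == "all_pairs":
        length += float(np.linalg.norm(c3 - c1))
    return length


@dataclass
class ShapeMetrics:
    """Per-record trajectory-shape summary."""

    record_id: str
    explored_area: float
    three_centroid_length: float
    centroid_mode: str
    ellipse_kind: str

    def to_row(self) -> dict:
        return {
            "record_id": self.record_id,
            "explored_area": self.explored_area,
            "three_centroid_length": self.three_centroid_length,
            "mode": self.centroid_mode,
            "ellipse_kind": self.ellipse_kind,
        }


def write_shapes(shapes: list[ShapeMetrics], path) -> None:
    pd.DataFrame([s.to_row() for s in shapes]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )
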