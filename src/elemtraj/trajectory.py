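"""Time-fixed moving windows and per-sample trajectory metrics.

Each sample anchors a window of fixed temporal width W — a set fraction
(default 30 %) of the record's span — containing every sample within W/2 years
of it.  Within each window three metrics describe the local trajectory of the
elemental composition through multivariate space:

* **turnover** — total beta diversity, the within-window multivariate variance
  ``BD = SS_total / (n - 1)``; equivalently the mean of squared pairwise
  Euclidean distances ``sum_{i<j} d_ij^2 / (n (n - 1))``.  High turnover means
  large compositional differences among the window's samples.  A percentile
  bootstrap (999 resamples by default) gives its confidence interval.
* **directionality** — the mean, over all ordered sample triplets i<j<k, of the
  angle at the middle sample (law of cosines on squared distances), scaled to
  [0, 1].  Collinear forward motion scores 1; immediate reversals score 0.
* **speed** — multivariate distance traversed per year.  The default "path"
  mode sums consecutive-segment distances and divides by W; "net" uses the
  first-to-last distance; "mean_segment" the mean consecutive-segment
  distance.  Speed is assigned to the mean year of the window's members.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FLOAT_FORMAT, AnalysisConfig, TransformedRecord

logger = logging.getLogger(__name__)

METRIC_NAMES = ("turnover", "directionality", "speed")


def window_width(span: tuple[float, float], fraction: float) -> int:
    """Moving-window width in whole years: ``floor(fraction * (max - min))``."""
    age_min, age_max = span
    if not age_max > age_min:
        raise ValueError(f"non-positive span ({age_min}, {age_max})")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return int(math.floor(fraction * (age_max - age_min)))


@dataclass(frozen=True)
class Window:
    """One centered moving window: the anchor sample, its age, the nominal
    width W (years) and the member sample indices (all samples within W/2
    years of the center, contiguous in stratigraphic order)."""

    center_index: int
    center_age: float
    width: float
    members: tuple[int, ...]
    sufficient: bool

    @property
    def n(self) -> int:
        return len(self.members)


def make_windows(trec: TransformedRecord, cfg: AnalysisConfig) -> list[Window]:
    """One window per sample, centered on the sample's year.

    Windows near the record edges keep the nominal width but are truncated by
    data availability.  Windows with fewer than ``cfg.min_window_n`` members
    are flagged insufficient (metrics for them are reported as missing).
    """
    W = window_width(trec.span, cfg.window_fraction)
    half = W / 2.0
    ages = trec.ages
    windows = []
    for i, a in enumerate(ages):
        members = tuple(int(j) for j in np.flatnonzero(np.abs(ages - a) <= half))
        windows.append(
            Window(
                center_index=i,
                center_age=float(a),
                width=float(W),
                members=members,
                sufficient=len(members) >= cfg.min_window_n,
            )
        )
    return windows


def turnover(win: Window, trec: TransformedRecord) -> float:
    """Total beta diversity of the window's samples: ``SS_total / (n - 1)``."""
    if win.n < 2:
        return float("nan")
    X = trec.values[list(win.members)]
    centered = X - X.mean(axis=0)
    return float((centered**2).sum() / (win.n - 1))


def turnover_ci(
    win: Window,
    trec: TransformedRecord,
    cfg: AnalysisConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Percentile 2.5/97.5 bootstrap interval of the window's turnover.

    Window members are resampled with replacement ``cfg.bootstrap_reps``
    times; resamples that happen to contain fewer than two distinct members
    simply yield zero turnover and are retained.
    """
    if win.n < 2:
        return float("nan"), float("nan")
    X = trec.values[list(win.members)]
    n = win.n
    idx = rng.integers(0, n, size=(cfg.bootstrap_reps, n))
    boots = np.empty(cfg.bootstrap_reps)
    for b in range(cfg.bootstrap_reps):
        Y = X[idx[b]]
        c = Y - Y.mean(axis=0)
        boots[b] = (c**2).sum() / (n - 1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(lo), float(hi)


def directionality(win: Window, trec: TransformedRecord) -> float:
    """Mean angle at the middle point over all ordered triplets, scaled to [0, 1].

    For members i<j<k the angle at j follows from the law of cosines on the
    squared Euclidean distances, with the cosine clamped to [-1, 1].  Triplets
    containing a zero-length segment are skipped (coincident compositions give
    no direction) and logged.
    """
    if win.n < 3:
        return float("nan")
    X = trec.values[list(win.members)]
    n = win.n
    D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    trip = np.array(list(itertools.combinations(range(n), 3)))
    i, j, k = trip[:, 0], trip[:, 1], trip[:, 2]
    dij2, djk2, dik2 = D2[i, j], D2[j, k], D2[i, k]
    valid = (dij2 > 0) & (djk2 > 0)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug("window at %.1f: skipped %d degenerate triplet(s)", win.center_age, n_skipped)
    if not valid.any():
        return float("nan")
    cos = (dij2[valid] + djk2[valid] - dik2[valid]) / (
        2.0 * np.sqrt(dij2[valid] * djk2[valid])
    )
    theta = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return float(theta.mean() / 180.0)


def speed(win: Window, trec: TransformedRecord, cfg: AnalysisConfig) -> tuple[float, float]:
    """Trajectory speed of the window, with the age it is assigned to.

    Returns ``(mean member age, value)``; the value is in multivariate
    distance units per year, computed per ``cfg.speed_mode``.
    """
    mean_age = float(trec.ages[list(win.members)].mean())
    if win.n < 2:
        return mean_age, float("nan")
    X = trec.values[list(win.members)]
    seg = np.sqrt(((np.diff(X, axis=0)) ** 2).sum(axis=1))
    W = win.width
    if cfg.speed_mode == "path":
        value = float(seg.sum() / W)
    elif cfg.speed_mode == "net":
        value = float(np.linalg.norm(X[-1] - X[0]) / W)
    else:  # mean_segment
        value = float(seg.mean() / W)
    return mean_age, value


@dataclass
class MetricSeries:
    """Per-window values of one trajectory metric, with configuration echo."""

    metric: str
    rows: pd.DataFrame  # columns: center_age, value, ci_lo, ci_hi, n
    window_width: float
    bootstrap_reps: int | None = None
    speed_mode: str | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.rows.copy()
        df.insert(0, "metric", self.metric)
        df["window_width"] = self.window_width
        return df


def compute_metrics(
    trec: TransformedRecord,
    cfg: AnalysisConfig,
    metrics: tuple[str, ...] = METRIC_NAMES,
    with_ci: bool = True,
) -> dict[str, MetricSeries]:
    """Compute the requested metric series over all windows of a record.

    Each metric applies its own minimum-n rule on top of the configured
    ``min_window_n`` flag: turnover needs n >= 2, directionality n >= 3,
    speed n >= 2.  Bootstrap CIs (turnover only) use a generator seeded from
    ``cfg.rng_seed`` so reruns are bit-identical.
    """
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    windows = make_windows(trec, cfg)
    rng = np.random.default_rng(cfg.rng_seed)
    out: dict[str, MetricSeries] = {}
    for metric in metrics:
        recs = []
        for win in windows:
            ok = win.sufficient
            if metric == "turnover":
                value = turnover(win, trec) if ok else float("nan")
                if with_ci and ok and np.isfinite(value):
                    ci_lo, ci_hi = turnover_ci(win, trec, cfg, rng)
                else:
                    ci_lo = ci_hi = float("nan")
                age = win.center_age
            elif metric == "directionality":
                value = directionality(win, trec) if ok else float("nan")
                ci_lo = ci_hi = float("nan")
                age = win.center_age
            else:
                age, value = speed(win, trec, cfg)
                if not ok:
                    value = float("nan")
                ci_lo = ci_hi = float("nan")
            recs.append(
                {"center_age": age, "value": value, "ci_lo": ci_lo, "ci_hi": ci_hi, "n": win.n}
            )
        rows = pd.DataFrame(recs).sort_values("center_age", kind="stable").reset_index(drop=True)
        out[metric] = MetricSeries(
            metric=metric,
            rows=rows,
            window_width=windows[0].width if windows else float("nan"),
            bootstrap_reps=cfg.bootstrap_reps if metric == "turnover" else None,
            speed_mode=cfg.speed_mode if metric == "speed" else None,
        )
    return out


def write_metrics(series: dict[str, MetricSeries], path) -> None:
    """Write metric series as one long CSV (metric, center_age, value, ...)."""
    frames = [series[m].to_frame() for m in METRIC_NAMES if m in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FORMAT)
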