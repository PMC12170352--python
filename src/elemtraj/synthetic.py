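"""Seeded generator of synthetic sediment-core elemental records.

Real dated lake records are multi-decadal to multi-millennial sequences of
10–16 positive element series (XRF counts per second, plus C and N in
dry-weight percent) that move through a small number of compositional
regimes: quasi-stable zones separated by abrupt or gradual transitions, with
measurement and sedimentological noise that scales with the signal.  The
generator emulates exactly that — piecewise zone means with optional
within-zone linear drift, abrupt or ramped transitions at known breakpoint
ages, and multiplicative lognormal noise (keeping values positive, as cps and
wt% must be) — and emits the ground truth (true breakpoint ages and zone
labels) alongside, so zonation- and metric-recovery experiments never peek at
generator internals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FLOAT_FORMAT, ElementRecord


@dataclass(frozen=True)
class ZoneSpec:
    """One compositional regime: its share of the record's duration, the mean
    level per element (raw units), and an optional per-element linear drift
    per year measured from the zone's start."""

    fraction: float
    means: tuple[float, ...]
    drift: tuple[float, ...] = ()

    def drift_vector(self, n_elements: int) -> np.ndarray:
        if not self.drift:
            return np.zeros(n_elements)
        return np.asarray(self.drift, dtype=float)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic record.

    span is (age_start, age_end) in years CE; spacing is "regular" or
    "jittered"; transition is "abrupt" or "ramp" (linear blend over
    ``ramp_tau`` years centered on each breakpoint); noise_sd is the standard
    deviation of the multiplicative lognormal noise on the log scale.
    """

    record_id: str
    age_start: float
    age_end: float
    n_samples: int
    elements: tuple[str, ...]
    zones: tuple[ZoneSpec, ...]
    spacing: str = "regular"
    transition: str = "abrupt"
    ramp_tau: float = 0.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.age_end <= self.age_start:
            raise ValueError("age_end must exceed age_start")
        if self.spacing not in ("regular", "jittered"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if self.transition not in ("abrupt", "ramp"):
            raise ValueError(f"unknown transition {self.transition!r}")
        if self.transition == "ramp" and self.ramp_tau <= 0:
            raise ValueError("ramp transition requires ramp_tau > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.zones:
            raise ValueError("at least one zone is required")
        total = sum(z.fraction for z in self.zones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"zone fractions must sum to 1, got {total}")
        p = len(self.elements)
        for z in self.zones:
            if len(z.means) != p:
                raise ValueError("every zone needs one mean per element")
            if any(m <= 0 for m in z.means):
                raise ValueError("zone mean levels must be positive")
            if z.drift and len(z.drift) != p:
                raise ValueError("drift vector length must match elements")

    @property
    def breakpoint_ages(self) -> list[float]:
        """True regime-boundary ages (internal zone boundaries)."""
        span = self.age_end - self.age_start
        edges = np.cumsum([z.fraction for z in self.zones])[:-1]
        return [float(self.age_start + f * span) for f in edges]


@dataclass
class GroundTruth:
    """Sidecar truth for a generated record."""

    breakpoint_ages: list[float]
    zone_labels: np.ndarray  # 1..n_zones per sample

    def to_frame(self, ages: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({"age_ce": ages, "true_zone": self.zone_labels})


def _sample_ages(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    ages = np.linspace(spec.age_start, spec.age_end, spec.n_samples)
    if spec.spacing == "jittered":
        step = ages[1] - ages[0]
        jitter = rng.uniform(-0.3, 0.3, size=spec.n_samples - 2) * step
        ages[1:-1] += jitter  # |jitter| < step/2 keeps ages strictly increasing
    return ages


def _zone_level(spec: SyntheticSpec, z: int, age: float, zone_starts: list[float]) -> np.ndarray:
    zone = spec.zones[z]
    level = np.asarray(zone.means, dtype=float)
    return level + zone.drift_vector(len(spec.elements)) * (age - zone_starts[z])


def generate(spec: SyntheticSpec) -> tuple[ElementRecord, GroundTruth]:
    """Generate a record and its ground truth, deterministically per seed.

    Each cell's expected log-level is the zone mean (plus within-zone drift,
    ramped linearly across transitions when requested) and the realized value
    multiplies that level by ``exp(eps)`` with ``eps ~ N(0, noise_sd^2)``
    independently per cell.
    """
    rng = np.random.default_rng(spec.seed)
    ages = _sample_ages(spec, rng)
    breaks = spec.breakpoint_ages
    zone_starts = [spec.age_start, *breaks]
    labels = np.searchsorted(breaks, ages, side="right") + 1
    p = len(spec.elements)
    levels = np.empty((spec.n_samples, p))
    for i, age in enumerate(ages):
        z = int(labels[i]) - 1
        level = _zone_level(spec, z, age, zone_starts)
        if spec.transition == "ramp":
            for bi, b in enumerate(breaks):
                if abs(age - b) <= spec.ramp_tau / 2:
                    lo = _zone_level(spec, bi, age, zone_starts)
                    hi = _zone_level(spec, bi + 1, age, zone_starts)
                    w = (age - (b - spec.ramp_tau / 2)) / spec.ramp_tau
                    level = (1 - w) * lo + w * hi
                    break
        levels[i] = level
    eps = rng.normal(0.0, spec.noise_sd, size=levels.shape)
    values = levels * np.exp(eps)
    record = ElementRecord(
        record_id=spec.record_id,
        ages=ages,
        elements=list(spec.elements),
        values=values,
    )
    return record, GroundTruth(breakpoint_ages=breaks, zone_labels=labels)


def write_truth(truth: GroundTruth, ages: np.ndarray, path) -> None:
    """Write the per-sample true zone labels as a sidecar CSV."""
    truth.to_frame(ages).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Base raw levels typical of XRF core-scanner counts (cps) and organic
#: dry-weight percents: major lithogenics in the 10^3–10^4 cps range, trace
#: elements 10^2–10^3, C a few percent, N under a percent.
_BASE_LEVELS = {
    "C": 6.0,
    "N": 0.6,
    "K": 12000.0,
    "Si": 30000.0,
    "Ca": 18000.0,
    "Ti": 4000.0,
    "V": 300.0,
    "Mn": 1200.0,
    "Fe": 45000.0,
    "Sr": 800.0,
    "Zr": 600.0,
    "Br": 400.0,
}

_PRESET_ELEMENTS = tuple(_BASE_LEVELS)
_TERRIGENOUS_IN_PRESET = ("K", "Si", "Ca", "Ti", "V", "Mn", "Fe", "Sr", "Zr")


def _zone_means(terr_factor: float, org_factor: float) -> tuple[float, ...]:
    out = []
    for e, base in _BASE_LEVELS.items():
        if e in ("C", "N"):
            out.append(base * org_factor)
        elif e in _TERRIGENOUS_IN_PRESET:
            out.append(base * terr_factor)
        else:
            out.append(base)
    return tuple(out)


def preset(name: str) -> SyntheticSpec:
    """Named, fully parameterized synthetic scenarios.

    * ``shallow_small`` — a small, shallow lake: short span, strong abrupt
      regime shifts (terrigenous pulses, organic depletion and recovery), the
      kind of record where trajectory shapes are large.
    * ``deep_large`` — a deep lake with a long span and muted, ramped
      transitions: smaller between-zone centroid separation by construction.
    * ``drift_only`` — a single regime with a slow monotone drift from a
      terrigenous-rich toward an organic-rich composition: high
      directionality, no true breakpoints.
    * ``stationary`` — one regime, no drift: pure noise about a fixed
      composition; zonation should find no support for k > 1.
    """
    p = len(_PRESET_ELEMENTS)
    if name == "shallow_small":
        return SyntheticSpec(
            record_id="shallow_small",
            age_start=1300.0,
            age_end=2000.0,
            n_samples=70,
            elements=_PRESET_ELEMENTS,
            zones=(
                ZoneSpec(0.4, _zone_means(1.0, 1.0)),
                ZoneSpec(0.35, _zone_means(2.2, 0.45)),
                ZoneSpec(0.25, _zone_means(0.8, 2.5)),
            ),
            transition="abrupt",
            noise_sd=0.10,
            seed=1301,
        )
    if name == "deep_large":
        return SyntheticSpec(
            record_id="deep_large",
            age_start=350.0,
            age_end=2000.0,
            n_samples=120,
            elements=_PRESET_ELEMENTS,
            zones=(
                ZoneSpec(0.4, _zone_means(1.0, 1.0)),
                ZoneSpec(0.35, _zone_means(1.35, 0.8)),
                ZoneSpec(0.25, _zone_means(0.9, 1.3)),
            ),
            transition="ramp",
            ramp_tau=80.0,
            noise_sd=0.10,
            seed=352,
        )
    if name == "drift_only":
        means = _zone_means(1.0, 1.0)
        # drift toward organic-rich: C and N climb, lithogenics decline, by
        # about +/-60 % of the base level over the 1000-year span
        drift = tuple(
            (0.0006 * m if e in ("C", "N") else -0.0006 * m if e in _TERRIGENOUS_IN_PRESET else 0.0)
            for e, m in zip(_PRESET_ELEMENTS, means)
        )
        return SyntheticSpec(
            record_id="drift_only",
            age_start=1000.0,
            age_end=2000.0,
            n_samples=60,
            elements=_PRESET_ELEMENTS,
            zones=(ZoneSpec(1.0, means, drift),),
            transition="abrupt",
            noise_sd=0.05,
            seed=1003,
        )
    if name == "stationary":
        return SyntheticSpec(
            record_id="stationary",
            age_start=1200.0,
            age_end=2000.0,
            n_samples=80,
            elements=_PRESET_ELEMENTS,
            zones=(ZoneSpec(1.0, _zone_means(1.0, 1.0)),),
            transition="abrupt",
            noise_sd=0.10,
            seed=1204,
        )
    raise KeyError(f"unknown preset {name!r}")


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """Same scenario, different random seed."""
    return dataclasses.replace(spec, seed=seed)
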