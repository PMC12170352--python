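"""Core domain types, table IO and validation for dated elemental records.

An :class:`ElementRecord` holds one sediment core's samples: a strictly
increasing sequence of calibrated calendar ages (years CE, oldest first) and
one non-negative measurement per declared element per sample.  XRF elements
are counts per second (cps); organic elements (C, N) are dry-weight percent.
All downstream stages (transformation, zonation, trajectory metrics) consume
these records or their transformed counterparts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default element classification: organic elements are biologically fixed,
#: terrigenous elements are lithogenic (catchment erosion / runoff).
ORGANIC_ELEMENTS = ("C", "N")
TERRIGENOUS_ELEMENTS = ("K", "Si", "Al", "Mn", "Fe", "Ti", "Zr", "V", "Sr", "Ca")

#: Age column name expected in input tables (calibrated calendar years CE).
AGE_COLUMN = "age_ce"

#: Repeatable float formatting for every CSV this package writes.
FLOAT_FORMAT = "%.12g"


class RecordValidationError(ValueError):
    """Base class for invalid record construction or file content."""


class MissingAgeColumnError(RecordValidationError):
    """The input table has no ``age_ce`` column."""


class NonNumericValueError(RecordValidationError):
    """A cell that should be numeric is not (or is missing/NaN)."""


class NegativeValueError(RecordValidationError):
    """An element measurement is negative (cps and wt% are non-negative)."""


class DuplicateAgeError(RecordValidationError):
    """Two samples share the same calibrated age."""


@dataclass(frozen=True)
class ElementMeta:
    """Classification of one element: its ecological class and measurement type."""

    element_class: str  # "organic" | "terrigenous" | "other"
    measurement: str  # "xrf_cps" | "weight_percent"

    def __post_init__(self) -> None:
        if self.element_class not in ("organic", "terrigenous", "other"):
            raise ValueError(f"unknown element class {self.element_class!r}")
        if self.measurement not in ("xrf_cps", "weight_percent"):
            raise ValueError(f"unknown measurement type {self.measurement!r}")


def default_element_meta(element: str) -> ElementMeta:
    """Default class/measurement for an element symbol.

    C and N are organic, measured as dry-weight percent; the standard
    lithogenic set is terrigenous XRF; anything else is "other" XRF.
    """
    if element in ORGANIC_ELEMENTS:
        return ElementMeta("organic", "weight_percent")
    if element in TERRIGENOUS_ELEMENTS:
        return ElementMeta("terrigenous", "xrf_cps")
    return ElementMeta("other", "xrf_cps")


@dataclass
class ElementRecord:
    """A dated, ordered sequence of samples x element measurements for one core.

    Parameters
    ----------
    record_id
        Identifier of the core/lake.
    ages
        Calibrated calendar ages in years CE, strictly increasing (oldest
        first), shape ``(n_samples,)``.
    elements
        Ordered element symbols, one per column of ``values``.
    values
        Non-negative measurements, shape ``(n_samples, n_elements)``.
    element_meta
        Per-element classification; defaults applied for missing entries.
    """

    record_id: str
    ages: np.ndarray
    elements: list[str]
    values: np.ndarray
    element_meta: dict[str, ElementMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.elements = list(self.elements)
        for e in self.elements:
            self.element_meta.setdefault(e, default_element_meta(e))
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.ages.ndim != 1:
            raise RecordValidationError("ages must be one-dimensional")
        n = self.ages.size
        if self.values.shape != (n, len(self.elements)):
            raise RecordValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples x {len(self.elements)} elements"
            )
        if np.any(~np.isfinite(self.ages)):
            raise NonNumericValueError(f"non-finite age in record {self.record_id!r}")
        diffs = np.diff(self.ages)
        if np.any(diffs == 0):
            i = int(np.argmax(diffs == 0))
            raise DuplicateAgeError(
                f"duplicate age {self.ages[i]} at rows {i} and {i + 1}"
            )
        if np.any(diffs < 0):
            raise RecordValidationError("ages must be strictly increasing (oldest first)")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            r, c = bad[0]
            raise NonNumericValueError(
                f"missing or non-numeric value at row {r} (age {self.ages[r]}), "
                f"column {self.elements[c]!r}"
            )
        neg = np.argwhere(self.values < 0)
        if neg.size:
            r, c = neg[0]
            raise NegativeValueError(
                f"negative value {self.values[r, c]} at row {r} "
                f"(age {self.ages[r]}), column {self.elements[c]!r}"
            )

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.ages.size)

    @property
    def span(self) -> tuple[float, float]:
        """(oldest age, youngest age) in years CE."""
        return float(self.ages[0]), float(self.ages[-1])

    def element_index(self, element: str) -> int:
        try:
            return self.elements.index(element)
        except ValueError:
            raise KeyError(f"record {self.record_id!r} has no element {element!r}")

    def series(self, element: str) -> np.ndarray:
        return self.values[:, self.element_index(element)]

    def xrf_elements(self) -> list[str]:
        return [e for e in self.elements if self.element_meta[e].measurement == "xrf_cps"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.elements)
        df.insert(0, AGE_COLUMN, self.ages)
        return df


@dataclass
class TransformedRecord:
    """An :class:`ElementRecord` after sqrt + min-max, all values in [0, 1].

    ``provenance`` maps element -> (min, max) of the square-rooted raw values
    used for rescaling; ``degenerate`` lists elements that were constant in the
    raw record and were mapped to all-zeros.
    """

    record_id: str
    ages: np.ndarray
    elements: list[str]
    values: np.ndarray
    provenance: dict[str, tuple[float, float]]
    degenerate: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.ages.size, len(self.elements)):
            raise RecordValidationError("transformed values shape mismatch")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise RecordValidationError("transformed values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(self.ages.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def restrict(self, elements: Sequence[str]) -> "TransformedRecord":
        """Restrict/reorder to the given element list (e.g. a common space)."""
        idx = [self.elements.index(e) for e in elements]
        return TransformedRecord(
            record_id=self.record_id,
            ages=self.ages.copy(),
            elements=list(elements),
            values=self.values[:, idx].copy(),
            provenance={e: self.provenance[e] for e in elements},
            degenerate={e for e in self.degenerate if e in elements},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.elements)
        df.insert(0, AGE_COLUMN, self.ages)
        return df


@dataclass
class AnalysisConfig:
    """Scalar settings shared across the pipeline.

    window_fraction
        Moving-window width as a fraction of the record's temporal span
        (default 0.30).
    min_window_n
        Minimum window occupancy for a metric value to be reported
        (default 4, i.e. requires n > 3).
    bootstrap_reps
        Bootstrap resamples for turnover confidence intervals (default 999).
    ellipse_level
        Coverage level of the explored-area confidence ellipse (default 0.95).
    n_zones
        Number of zones to cut from the CONISS tree (>= 2).
    speed_mode
        "path" (traversed distance per year, default), "net"
        (first-to-last distance per year) or "mean_segment".
    centroid_length_mode
        "chronological" (default) or "all_pairs".
    rng_seed
        Seed for every stochastic step (bootstrap, simulation).
    """

    window_fraction: float = 0.30
    min_window_n: int = 4
    bootstrap_reps: int = 999
    ellipse_level: float = 0.95
    n_zones: int = 3
    speed_mode: str = "path"
    centroid_length_mode: str = "chronological"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")
        if self.min_window_n < 1:
            raise ValueError("min_window_n must be >= 1")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if not 0 < self.ellipse_level < 1:
            raise ValueError("ellipse_level must be in (0, 1)")
        if self.n_zones < 2:
            raise ValueError("n_zones must be >= 2")
        if self.speed_mode not in ("path", "net", "mean_segment"):
            raise ValueError(f"unknown speed_mode {self.speed_mode!r}")
        if self.centroid_length_mode not in ("chronological", "all_pairs"):
            raise ValueError(f"unknown centroid_length_mode {self.centroid_length_mode!r}")


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_element_meta(path: str | Path) -> dict[str, ElementMeta]:
    """Read a sidecar metadata CSV with columns element, class, measurement."""
    df = _read_table(Path(path))
    required = {"element", "class", "measurement"}
    if not required.issubset(df.columns):
        raise RecordValidationError(
            f"metadata file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return {
        str(row["element"]): ElementMeta(str(row["class"]), str(row["measurement"]))
        for _, row in df.iterrows()
    }


def read_record(
    path: str | Path,
    element_meta: Mapping[str, ElementMeta] | None = None,
    record_id: str | None = None,
    drop_incomplete: bool = False,
) -> ElementRecord:
    """Read a wide-format sample table (CSV/TSV) into an :class:`ElementRecord`.

    The table must contain an ``age_ce`` column plus one numeric column per
    element.  Rows are sorted oldest-to-youngest.  Missing cells are an error
    unless ``drop_incomplete`` is set, in which case incomplete samples are
    dropped with a warning.
    """
    path = Path(path)
    df = _read_table(path)
    if AGE_COLUMN not in df.columns:
        raise MissingAgeColumnError(
            f"{path.name}: no {AGE_COLUMN!r} column (found {list(df.columns)})"
        )
    element_cols = [c for c in df.columns if c != AGE_COLUMN]
    if len(element_cols) < 2:
        raise RecordValidationError(f"{path.name}: need at least 2 element columns")
    for col in [AGE_COLUMN, *element_cols]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            r = int(bad.idxmax())
            raise NonNumericValueError(
                f"{path.name}: non-numeric value {df[col][r]!r} at row {r}, column {col!r}"
            )
        df[col] = coerced
    if drop_incomplete:
        incomplete = df[element_cols].isna().any(axis=1) | df[AGE_COLUMN].isna()
        if incomplete.any():
            logger.warning(
                "%s: dropping %d incomplete sample(s)", path.name, int(incomplete.sum())
            )
            df = df[~incomplete].reset_index(drop=True)
    df = df.sort_values(AGE_COLUMN, kind="stable").reset_index(drop=True)
    meta = dict(element_meta) if element_meta else {}
    return ElementRecord(
        record_id=record_id or path.stem,
        ages=df[AGE_COLUMN].to_numpy(),
        elements=element_cols,
        values=df[element_cols].to_numpy(),
        element_meta=meta,
    )


def write_record(record: ElementRecord | TransformedRecord, path: str | Path) -> None:
    """Write a record (raw or transformed) as a flat CSV."""
    record.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_transformed(path: str | Path, record_id: str | None = None) -> TransformedRecord:
    """Read a previously written transformed record.

    Provenance cannot be recovered from the flat table; it is recorded as the
    identity interval (0, 1) per element.
    """
    path = Path(path)
    df = _read_table(path)
    if AGE_COLUMN not in df.columns:
        raise MissingAgeColumnError(f"{path.name}: no {AGE_COLUMN!r} column")
    elements = [c for c in df.columns if c != AGE_COLUMN]
    return TransformedRecord(
        record_id=record_id or path.stem,
        ages=df[AGE_COLUMN].to_numpy(dtype=float),
        elements=elements,
        values=df[elements].to_numpy(dtype=float),
        provenance={e: (0.0, 1.0) for e in elements},
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table with the package's repeatable float formatting."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
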