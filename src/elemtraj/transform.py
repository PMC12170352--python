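"""The elementome transformation chain and element-subset construction.

Raw element series live on wildly different scales (XRF counts per second vs
dry-weight percent), so each series is square-root transformed — damping the
influence of high-count elements — and then min–max rescaled to [0, 1] within
its record.  After this double transformation every element contributes on a
comparable relative scale; values are interpreted relative to the record, not
as absolute concentrations.

Subsets support the robustness scenario of analysing XRF data alone (dropping
C and N) and the construction of a common multivariate space across several
records that share a core set of elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .core import ElementRecord, TransformedRecord

logger = logging.getLogger(__name__)

#: Elements shared by all five study lakes, used for the joint multivariate space.
COMMON_ELEMENTS = ("C", "N", "K", "Fe", "Mn", "Ti", "Zr", "V", "Si", "Sr", "Ca")


class SubsetError(ValueError):
    """Element subset resolution failed (empty or unresolvable)."""


@dataclass(frozen=True)
class ElementSubsetSpec:
    """Which elements of a record enter the analysis.

    mode
        "all" — every declared element; "xrf_only" — only elements measured as
        XRF cps (drops C, N and any other weight-percent series); "explicit" —
        the given list, which must be a subset of the record's elements.
    elements
        Explicit list (mode "explicit") or, for multi-record spaces, the
        ordered common-element list.
    """

    mode: str = "all"
    elements: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("all", "xrf_only", "explicit"):
            raise SubsetError(f"unknown subset mode {self.mode!r}")
        if self.mode == "explicit" and not self.elements:
            raise SubsetError("explicit subset requires a non-empty element list")

    def resolve(self, record: ElementRecord) -> list[str]:
        """Resolve to an ordered element list for this record."""
        if self.mode == "all":
            out = list(record.elements)
        elif self.mode == "xrf_only":
            out = record.xrf_elements()
        else:
            missing = [e for e in self.elements if e not in record.elements]
            if missing:
                raise SubsetError(
                    f"record {record.record_id!r} lacks elements {missing}"
                )
            out = list(self.elements)
        if not out:
            raise SubsetError(
                f"empty element subset for record {record.record_id!r} (mode {self.mode!r})"
            )
        return out


def sqrt_minmax(
    record: ElementRecord, subset: ElementSubsetSpec | None = None
) -> TransformedRecord:
    """Apply the sqrt + min–max transformation to (a subset of) a record.

    Each retained element series y is mapped to
    ``z = (sqrt(y) - min) / (max - min)`` with min/max taken over this record's
    square-rooted values, so z spans exactly [0, 1].  Constant series carry no
    compositional signal; they are mapped to all-zeros and flagged degenerate
    (rather than NaN) so downstream Euclidean distances stay defined.
    """
    subset = subset or ElementSubsetSpec("all")
    elements = subset.resolve(record)
    idx = [record.element_index(e) for e in elements]
    sq = np.sqrt(record.values[:, idx])
    lo = sq.min(axis=0)
    hi = sq.max(axis=0)
    rng = hi - lo
    degenerate = {elements[j] for j in np.flatnonzero(rng == 0)}
    for e in degenerate:
        logger.warning(
            "record %s: element %s is constant; mapped to zeros", record.record_id, e
        )
    safe = np.where(rng == 0, 1.0, rng)
    z = (sq - lo) / safe
    z[:, rng == 0] = 0.0
    return TransformedRecord(
        record_id=record.record_id,
        ages=record.ages.copy(),
        elements=elements,
        values=z,
        provenance={e: (float(lo[j]), float(hi[j])) for j, e in enumerate(elements)},
        degenerate=degenerate,
    )


def common_elements(records: Sequence[ElementRecord]) -> list[str]:
    """Elements present in every record, in the canonical common-space order
    (the shared study list first, then any extras in first-record order)."""
    shared = set(records[0].elements)
    for r in records[1:]:
        shared &= set(r.elements)
    ordered = [e for e in COMMON_ELEMENTS if e in shared]
    ordered += [e for e in records[0].elements if e in shared and e not in ordered]
    return ordered


def build_common_space(
    records: Sequence[ElementRecord], subset: ElementSubsetSpec | None = None
) -> list[TransformedRecord]:
    """Transform several records into one shared element ordering.

    Each record is transformed independently — min–max within its own record,
    because XRF cps are instrument- and core-specific and not comparable in
    absolute terms across cores — then restricted and reordered to the common
    element list.  Records remain separable by ``record_id``.
    """
    if len(records) < 2:
        raise ValueError("a common space needs at least 2 records")
    if subset is not None and subset.elements:
        elems = list(subset.elements)
        for r in records:
            missing = [e for e in elems if e not in r.elements]
            if missing:
                raise SubsetError(f"record {r.record_id!r} lacks elements {missing}")
    else:
        elems = common_elements(records)
        if not elems:
            raise SubsetError("records share no common elements")
    return [sqrt_minmax(r, ElementSubsetSpec("explicit", tuple(elems))) for r in records]


def pooled_matrix(trecs: Sequence[TransformedRecord]) -> tuple[np.ndarray, list[str]]:
    """Stack common-space records row-wise; returns (matrix, record_id per row)."""
    elems = trecs[0].elements
    for t in trecs[1:]:
        if t.elements != elems:
            raise ValueError("records do not share one element ordering")
    X = np.vstack([t.values for t in trecs])
    ids = [t.record_id for t in trecs for _ in range(t.n_samples)]
    return X, ids


@dataclass
class ElementClustering:
    """Ward merge tree over element time-series.

    ``linkage_matrix`` follows the scipy convention (rows: merged cluster ids,
    height, member count); heights are Ward/Euclidean merge distances.
    """

    elements: list[str]
    linkage_matrix: np.ndarray


def cluster_element_series(trec: TransformedRecord) -> ElementClustering:
    """Hierarchically cluster element time-series (Ward linkage, Euclidean).

    Elements are the observations and samples the dimensions, so elements that
    co-vary through time merge early — revealing, e.g., the organic (C, N) vs
    terrigenous split.  Degenerate elements are excluded.
    """
    usable = [e for e in trec.elements if e not in trec.degenerate]
    if len(usable) < 2:
        raise ValueError("need at least 2 non-degenerate elements to cluster")
    idx = [trec.elements.index(e) for e in usable]
    X = trec.values[:, idx].T  # elements x samples
    Z = linkage(X, method="ward", metric="euclidean")
    return ElementClustering(elements=usable, linkage_matrix=Z)
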