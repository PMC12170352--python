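"""Stratigraphically constrained zonation of transformed records.

CONISS (constrained incremental sum of squares) is agglomerative clustering in
which only stratigraphically adjacent clusters may merge: at each step the
adjacent pair whose fusion least increases the total within-cluster dispersion
(sum of squared Euclidean deviations from cluster means) is merged.  Cutting
the resulting tree at k clusters yields k contiguous zones and k-1 breakpoint
age intervals.  A broken-stick comparison of merge-cost increments gives an
advisory zone count; in practice k is chosen per record against independent
phase schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import rand_score

from .core import FLOAT_FORMAT, TransformedRecord


@dataclass(frozen=True)
class MergeStep:
    """One CONISS merge: the two adjacent clusters (as sample-index ranges,
    inclusive), the dispersion increment it costs, and the cumulative
    within-cluster sum of squares after the merge."""

    left: tuple[int, int]
    right: tuple[int, int]
    cost: float
    cumulative: float


@dataclass
class Zonation:
    """CONISS merge tree for one record, optionally cut into k zones.

    ``zone_labels`` (1..k, non-decreasing along the stratigraphic order) and
    ``breakpoints`` (age intervals between the boundary samples of adjacent
    zones) are populated by :func:`cut_zones`.
    """

    record_id: str
    ages: np.ndarray
    merge_steps: list[MergeStep]
    k: int | None = None
    zone_labels: np.ndarray | None = None
    breakpoints: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return int(self.ages.size)

    @property
    def total_dispersion(self) -> float:
        """Total sum of squares about the grand mean (= last cumulative cost)."""
        return self.merge_steps[-1].cumulative if self.merge_steps else 0.0

    def increments(self) -> np.ndarray:
        return np.array([s.cost for s in self.merge_steps])

    def labels_frame(self) -> pd.DataFrame:
        if self.zone_labels is None:
            raise ValueError("zonation has not been cut; call cut_zones first")
        return pd.DataFrame({"age_ce": self.ages, "zone": self.zone_labels})

    def breakpoints_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"breakpoint": i + 1, "age_lo": lo, "age_hi": hi}
                for i, (lo, hi) in enumerate(self.breakpoints)
            ]
        )


def _segment_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums of X and of ||x||^2, for O(1) segment dispersion queries."""
    csum = np.vstack([np.zeros(X.shape[1]), np.cumsum(X, axis=0)])
    csq = np.concatenate([[0.0], np.cumsum((X**2).sum(axis=1))])
    return csum, csq


def _segment_ss(csum: np.ndarray, csq: np.ndarray, a: int, b: int) -> float:
    """Within-cluster sum of squares of samples a..b inclusive."""
    n = b - a + 1
    s = csum[b + 1] - csum[a]
    return float(csq[b + 1] - csq[a] - (s @ s) / n)


def coniss(trec: TransformedRecord) -> Zonation:
    """Build the CONISS merge tree of a transformed record.

    Clusters are contiguous sample runs; the merge cost of two adjacent runs
    equals the increase in within-cluster sum of squares their fusion causes.
    Ties are broken by merging the stratigraphically uppermost (oldest) pair,
    making the output deterministic.  The cumulative cost after the final
    merge equals the total dispersion of the data about its grand mean.
    """
    n = trec.n_samples
    if n < 2:
        raise ValueError("CONISS needs at least 2 samples")
    X = trec.values
    csum, csq = _segment_stats(X)
    # active clusters as inclusive index ranges, in stratigraphic order
    segs: list[tuple[int, int]] = [(i, i) for i in range(n)]
    ss = [0.0] * n  # within-cluster SS per active cluster
    steps: list[MergeStep] = []
    cumulative = 0.0
    while len(segs) > 1:
        best_j = -1
        best_cost = np.inf
        for j in range(len(segs) - 1):
            a0, _ = segs[j]
            _, b1 = segs[j + 1]
            cost = _segment_ss(csum, csq, a0, b1) - ss[j] - ss[j + 1]
            if cost < best_cost - 1e-15:  # strict improvement; ties keep oldest
                best_cost = cost
                best_j = j
        j = best_j
        left, right = segs[j], segs[j + 1]
        merged = (left[0], right[1])
        merged_ss = _segment_ss(csum, csq, merged[0], merged[1])
        cumulative += best_cost
        steps.append(MergeStep(left=left, right=right, cost=max(best_cost, 0.0), cumulative=cumulative))
        segs[j : j + 2] = [merged]
        ss[j : j + 2] = [merged_ss]
    return Zonation(record_id=trec.record_id, ages=trec.ages.copy(), merge_steps=steps)


def cut_zones(zon: Zonation, k: int) -> Zonation:
    """Cut the merge tree into k contiguous zones (undo the last k-1 merges).

    Returns a new :class:`Zonation` with zone labels 1..k in stratigraphic
    order and breakpoints reported as the age interval between the last sample
    of one zone and the first sample of the next — matching how shift ages are
    conventionally reported as intervals.
    """
    n = zon.n_samples
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    # each merge removes the boundary between left and right; after the first
    # n-k merges, k-1 boundaries remain
    removed = {step.right[0] for step in zon.merge_steps[: n - k]}
    boundaries = sorted(set(range(1, n)) - removed)
    labels = np.ones(n, dtype=int)
    for b in boundaries:
        labels[b:] += 1
    breakpoints = [(float(zon.ages[b - 1]), float(zon.ages[b])) for b in boundaries]
    return Zonation(
        record_id=zon.record_id,
        ages=zon.ages.copy(),
        merge_steps=list(zon.merge_steps),
        k=k,
        zone_labels=labels,
        breakpoints=breakpoints,
    )


def broken_stick(zon: Zonation) -> int:
    """Advisory zone count from a broken-stick comparison.

    The dispersion reduction achieved in moving from k-1 to k zones (the cost
    of the merge undone at that step) is compared with the broken-stick
    expectation for the (k-1)-th largest of n-1 random pieces of the total
    dispersion.  The suggested k is the largest k (scanning k = 2 upward)
    whose observed reduction exceeds the expectation; 1 if none does.
    """
    n = zon.n_samples
    total = zon.total_dispersion
    # transformed data span [0,1]; dispersion below this is numerical noise
    if total <= 1e-10:
        return 1
    m = n - 1  # number of merges / pieces
    # expected share of the j-th largest of m broken-stick pieces
    harmonic = np.cumsum(1.0 / np.arange(m, 0, -1))[::-1]  # sum_{i=j}^{m} 1/i
    k_best = 1
    for k in range(2, n + 1):
        observed = zon.merge_steps[n - k].cost  # reduction from k-1 to k zones
        expected = total / m * harmonic[k - 2]
        if observed > expected:
            k_best = k
        else:
            break
    return k_best


@dataclass
class ZoneComparison:
    """Agreement between two zonations of the same sample grid.

    ``matched_offsets`` pairs each breakpoint of ``a`` with its greedily
    nearest breakpoint of ``b`` (signed years, b minus a); ``agreement`` is
    the Rand index of the two zone labelings over all sample pairs.
    """

    offsets: list[tuple[float, float, float]]  # (age_a, age_b, signed offset b-a)
    agreement: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.offsets, columns=["age_a", "age_b", "offset_years"])


def compare_zonations(a: Zonation, b: Zonation) -> ZoneComparison:
    """Compare two cut zonations on the same sample grid.

    Breakpoints are matched greedily by absolute age offset (interval
    midpoints); agreement is the Rand index over zone-label co-membership.
    """
    if a.zone_labels is None or b.zone_labels is None:
        raise ValueError("both zonations must be cut before comparison")
    if a.n_samples != b.n_samples:
        raise ValueError("zonations are on different sample grids")
    mids_a = [0.5 * (lo + hi) for lo, hi in a.breakpoints]
    mids_b = [0.5 * (lo + hi) for lo, hi in b.breakpoints]
    pairs = sorted(
        ((abs(mb - ma), i, j) for i, ma in enumerate(mids_a) for j, mb in enumerate(mids_b)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    offsets: list[tuple[float, float, float]] = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        offsets.append((mids_a[i], mids_b[j], mids_b[j] - mids_a[i]))
    offsets.sort(key=lambda t: t[0])
    agreement = float(rand_score(a.zone_labels, b.zone_labels))
    return ZoneComparison(offsets=offsets, agreement=agreement)


def write_zonation(zon: Zonation, labels_path, breakpoints_path) -> None:
    """Write per-sample zone labels and the breakpoint intervals as CSVs."""
    zon.labels_frame().to_csv(labels_path, index=False, float_format=FLOAT_FORMAT)
    zon.breakpoints_frame().to_csv(breakpoints_path, index=False, float_format=FLOAT_FORMAT)
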