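"""Exact N-way Venn (exclusive-region) partitions of labelled sets.

Shared by the k-mer attribution and plastid SNP-sharing stages.  A region is
identified by the *exact* subset of input sets its elements belong to, so the
regions are disjoint and partition the union — an invariant checked on
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["OverlapPartition", "venn_from_sets", "venn_from_arrays"]


@dataclass(frozen=True)
class OverlapPartition:
    """Counts of elements in every exclusive region of an N-set Venn.

    Attributes
    ----------
    set_labels
        Ordered labels of the input sets (2–6 of them).
    region_counts
        Mapping from each non-empty label subset (``frozenset``) to the
        number of elements present in exactly those sets.  Subsets with
        zero elements are included with count 0.
    set_sizes
        Size of each input set; redundant with the regions but convenient.
    """

    set_labels: tuple[str, ...]
    region_counts: Mapping[frozenset, int]
    set_sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = set(self.set_labels)
        for region in self.region_counts:
            if not region or not region <= labels:
                raise ValueError(f"invalid region {set(region)!r} for labels {labels!r}")
        # partition invariant: regions containing L must sum to |L|
        for lab, size in self.set_sizes.items():
            got = sum(c for r, c in self.region_counts.items() if lab in r)
            if got != size:
                raise ValueError(
                    f"region counts for {lab!r} sum to {got}, expected set size {size}"
                )

    def count(self, *labels: str) -> int:
        """Count of the exclusive region containing exactly ``labels``."""
        return int(self.region_counts.get(frozenset(labels), 0))

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def marginal(self, label: str) -> int:
        """Total size of one input set (sum of regions containing it)."""
        return sum(c for r, c in self.region_counts.items() if label in r)

    def percentages(self, focal: str) -> dict[frozenset, float]:
        """Per-region percentages of the *focal* set's size.

        Mirrors single-species Venn figures: each region containing the
        focal set expressed as ``100 * count / |focal set|``.
        """
        total = self.marginal(focal)
        if total == 0:
            raise ValueError(f"focal set {focal!r} is empty")
        return {
            r: 100.0 * c / total for r, c in self.region_counts.items() if focal in r
        }

    def to_rows(self) -> list[dict]:
        """Tabular form: one row per region, sorted for deterministic output."""
        rows = []
        for region in sorted(self.region_counts, key=lambda r: (len(r), sorted(r))):
            rows.append(
                {
                    "region": "+".join(sorted(region)),
                    "count": int(self.region_counts[region]),
                    "percent_of_union": (
                        100.0 * self.region_counts[region] / self.union_size
                        if self.union_size
                        else 0.0
                    ),
                }
            )
        return rows


def _all_regions(labels: Sequence[str]) -> list[frozenset]:
    n = len(labels)
    return [
        frozenset(labels[i] for i in range(n) if bits >> i & 1)
        for bits in range(1, 1 << n)
    ]


def _validate_labels(labels: Sequence[str]) -> None:
    if not 2 <= len(labels) <= 6:
        raise ValueError(f"need between 2 and 6 sets, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be unique")


def venn_from_sets(sets: Mapping[str, Iterable]) -> OverlapPartition:
    """Exclusive-region counts for generic hashable elements."""
    labels = list(sets)
    _validate_labels(labels)
    as_sets = {lab: set(v) for lab, v in sets.items()}
    masks: dict[object, int] = {}
    for i, lab in enumerate(labels):
        for x in as_sets[lab]:
            masks[x] = masks.get(x, 0) | (1 << i)
    counts = {r: 0 for r in _all_regions(labels)}
    for bits in masks.values():
        region = frozenset(labels[i] for i in range(len(labels)) if bits >> i & 1)
        counts[region] += 1
    return OverlapPartition(
        tuple(labels), counts, {lab: len(s) for lab, s in as_sets.items()}
    )


def venn_from_arrays(sets: Mapping[str, np.ndarray]) -> OverlapPartition:
    """Exclusive-region counts for sorted unique numpy arrays (fast path)."""
    labels = list(sets)
    _validate_labels(labels)
    arrays = {lab: np.asarray(a) for lab, a in sets.items()}
    nonempty = [a for a in arrays.values() if a.size]
    if not nonempty:
        counts = {r: 0 for r in _all_regions(labels)}
        return OverlapPartition(tuple(labels), counts, {lab: 0 for lab in labels})
    union = np.unique(np.concatenate(nonempty))
    mask = np.zeros(union.size, dtype=np.uint8)
    for i, lab in enumerate(labels):
        a = arrays[lab]
        if a.size:
            member = np.isin(union, a, assume_unique=True)
            mask |= member.astype(np.uint8) << np.uint8(i)
    bincounts = np.bincount(mask, minlength=1 << len(labels))
    counts = {}
    for bits in range(1, 1 << len(labels)):
        region = frozenset(labels[i] for i in range(len(labels)) if bits >> i & 1)
        counts[region] = int(bincounts[bits])
    return OverlapPartition(
        tuple(labels), counts, {lab: int(arrays[lab].size) for lab in labels}
    )
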