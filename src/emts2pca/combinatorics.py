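"""Constrained enumeration of 10-sample combinatorial designs.

From each subgroup of the learning split, all half-matrices of k samples
(default 5) are enumerated, those homogeneous in the confounder (etiology)
are removed, and a greedy scan retains a set of half-matrices any two of
which share at most ``max_shared`` samples (default floor(k/2) = 2, i.e. a
>50% difference in composition).  The Cartesian product of the retained
half-matrices of the two subgroups forms the 10-sample designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from .data_model import DataError, SampleMetadata

logger = logging.getLogger("emts2pca")

__all__ = [
    "HalfMatrix",
    "TenSampleDesign",
    "enumerate_half_matrices",
    "filter_confounder",
    "filter_overlap",
    "build_designs",
]


@dataclass(frozen=True)
class HalfMatrix:
    group: str
    sample_ids: tuple[str, ...]  # sorted, distinct

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError(f"half-matrix has repeated samples: {self.sample_ids}")
        object.__setattr__(self, "sample_ids", tuple(sorted(self.sample_ids)))


@dataclass(frozen=True)
class TenSampleDesign:
    half_a: HalfMatrix
    half_b: HalfMatrix

    def __post_init__(self) -> None:
        if self.half_a.group == self.half_b.group:
            raise DataError("design halves must come from different groups")
        if set(self.half_a.sample_ids) & set(self.half_b.sample_ids):
            raise DataError("design halves share samples")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.half_a.sample_ids + self.half_b.sample_ids

    @property
    def groups(self) -> tuple[str, str]:
        return (self.half_a.group, self.half_b.group)


def enumerate_half_matrices(
    group: str, group_samples: list[str], k: int = 5
) -> list[HalfMatrix]:
    """All C(n, k) half-matrices of a subgroup, in lexicographic order of
    sorted sample ids."""
    if len(group_samples) < k:
        raise DataError(
            f"group {group!r} has {len(group_samples)} samples, fewer than k={k}"
        )
    ordered = sorted(group_samples)
    return [HalfMatrix(group, combo) for combo in combinations(ordered, k)]


def filter_confounder(
    halves: list[HalfMatrix], meta: SampleMetadata
) -> list[HalfMatrix]:
    """Drop half-matrices whose samples all share one confounder level.

    Without a confounder column the filter is a logged no-op.
    """
    if not meta.has_confounder:
        logger.info("filter_confounder: no confounder labels; filter skipped")
        return list(halves)
    kept: list[HalfMatrix] = []
    for h in halves:
        levels = {meta.confounder_of(s) for s in h.sample_ids}
        if len(levels) >= 2:
            kept.append(h)
        else:
            logger.debug(
                "filter_confounder: dropped %s (single level %s)",
                h.sample_ids, levels,
            )
    logger.info(
        "filter_confounder: kept %d/%d half-matrices", len(kept), len(halves)
    )
    return kept


def filter_overlap(
    halves: list[HalfMatrix], max_shared: int | None = None
) -> list[HalfMatrix]:
    """Greedy maximal set of half-matrices pairwise sharing <= max_shared
    samples, scanning the deterministic enumeration order.

    The default ``max_shared = floor(k/2)`` encodes a >50% difference in
    composition between any two retained half-matrices.
    """
    if not halves:
        return []
    k = len(halves[0].sample_ids)
    if max_shared is None:
        max_shared = k // 2
    kept: list[HalfMatrix] = []
    kept_sets: list[set[str]] = []
    for h in halves:
        s = set(h.sample_ids)
        if all(len(s & t) <= max_shared for t in kept_sets):
            kept.append(h)
            kept_sets.append(s)
    logger.info(
        "filter_overlap: kept %d/%d half-matrices (max_shared=%d)",
        len(kept), len(halves), max_shared,
    )
    return kept


def build_designs(
    halves_a: list[HalfMatrix],
    halves_b: list[HalfMatrix],
    learning_samples: list[str] | None = None,
) -> list[TenSampleDesign]:
    """Cartesian product of retained half-matrices of the two subgroups.

    If ``learning_samples`` is given, a coverage check warns about any
    learning sample absent from every design (the half-matrix size is chosen
    so that each learning sample appears in at least one design).
    """
    if not halves_a or not halves_b:
        raise DataError("both half-matrix lists must be non-empty")
    designs = [TenSampleDesign(a, b) for a in halves_a for b in halves_b]
    if learning_samples is not None:
        covered: set[str] = set()
        for d in designs:
            covered.update(d.sample_ids)
        missing = sorted(set(learning_samples) - covered)
        if missing:
            logger.warning(
                "build_designs: learning samples in no design: %s", missing
            )
    logger.info("build_designs: %d designs", len(designs))
    return designs
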