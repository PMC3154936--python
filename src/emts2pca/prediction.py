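"""Case-by-case classification of testing samples in the validation space.

The eigendecomposition of ξ′ (the standardized matrix restricted to the
learning samples) defines the validation space; every column of ξ is
projected onto those eigenvectors to give coordinates Ψ.  Testing samples
are classified by the RMS rules against the learning samples, with an
escalation path for outliers: top-3 axes, then all axes, then the
eigenvector subset maximizing the between-group to within-group variance
ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data_model import (
    ATTRIBUTED_A,
    ATTRIBUTED_B,
    ClassificationReport,
    DataError,
    SampleDecision,
    UNATTRIBUTED,
)
from .signature import StandardizedMatrix
from .training import build_pca_space, build_rms_profile, classify_by_rms

logger = logging.getLogger("emts2pca")

__all__ = [
    "ValidationSpace",
    "EigenSubsetScore",
    "build_validation_space",
    "classify_testing",
    "select_axis_subset",
    "reclassify_with_subset",
    "classify_all_testing",
]


@dataclass
class ValidationSpace:
    """Validation coordinate system and the projected coordinates Ψ.

    The eigenstructure comes from ξ′ alone, so learning-sample coordinates
    are independent of which testing samples are projected.
    """

    sample_ids: list[str]
    learning_ids: list[str]
    learning_is_a: np.ndarray     # aligned with learning_ids
    psi: np.ndarray               # all samples x axes
    eigenvalues: np.ndarray
    groups: tuple[str, str]
    n_axes_default: int = 3

    @property
    def n_axes(self) -> int:
        return self.psi.shape[1]

    @property
    def learning_coords(self) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in self.learning_ids]
        return self.psi[idx]

    def coords_of(self, sample_id: str) -> np.ndarray:
        return self.psi[self.sample_ids.index(sample_id)]


def build_validation_space(
    std: StandardizedMatrix,
    learning_is_a: dict[str, bool],
    groups: tuple[str, str] = ("A", "B"),
    n_axes_default: int = 3,
) -> ValidationSpace:
    """Eigendecomposition of ξ′; projection of every ξ column onto it."""
    xi_prime = std.xi_prime
    if xi_prime.shape[0] < 2:
        raise DataError("need >= 2 signature genes for the validation space")
    if np.linalg.matrix_rank(xi_prime) < 2:
        raise DataError("degenerate ξ′ (rank < 2)")
    is_a = np.array([learning_is_a[s] for s in std.learning_ids])
    if is_a.all() or not is_a.any():
        raise DataError("both groups must be present among learning samples")
    space = build_pca_space(xi_prime, n_axes_default=n_axes_default)
    psi = space.project(std.values)
    return ValidationSpace(
        sample_ids=list(std.sample_ids),
        learning_ids=list(std.learning_ids),
        learning_is_a=is_a,
        psi=psi,
        eigenvalues=space.eigenvalues,
        groups=groups,
        n_axes_default=n_axes_default,
    )


def classify_testing(
    space: ValidationSpace,
    sample_id: str,
    axes: list[int] | None = None,
    sd_multiplier: float = 1.0,
) -> SampleDecision:
    """RMS decision for one projected sample over the chosen axes (default:
    the leading ``n_axes_default``)."""
    if axes is None:
        axes = list(range(min(space.n_axes_default, space.n_axes)))
    prof = build_rms_profile(
        space.learning_coords, space.learning_is_a, space.coords_of(sample_id), axes
    )
    decision = classify_by_rms(prof, sd_multiplier=sd_multiplier)
    return SampleDecision(
        sample_id=sample_id,
        decision=decision,
        rms_a=prof.rms_a_class,
        rms_b=prof.rms_b_class,
        axes=list(axes),
    )


@dataclass
class EigenSubsetScore:
    """Score of one eigenvector subset: between-centroid variance over the
    summed within-group variances of the learning coordinates."""

    axes: tuple[int, ...]
    v_inter: float
    v_within_sum: float

    @property
    def ratio(self) -> float:
        return self.v_inter / self.v_within_sum if self.v_within_sum > 0 else np.inf


def variance_decomposition(
    coords: np.ndarray, is_a: np.ndarray, axes: list[int] | tuple[int, ...]
) -> tuple[float, float, float]:
    """Population-weighted decomposition over the chosen axes.

    Returns ``(v_inter, v_within_sum, v_total)`` with
    ``v_total = v_inter + v_within_sum`` exactly (population variances,
    group terms weighted by group size / total).
    """
    sub = coords[:, list(axes)]
    n = sub.shape[0]
    mu = sub.mean(axis=0)
    v_total = float(((sub - mu) ** 2).sum() / n)
    v_inter = 0.0
    v_within = 0.0
    for mask in (np.asarray(is_a, bool), ~np.asarray(is_a, bool)):
        g = sub[mask]
        w = g.shape[0] / n
        mu_g = g.mean(axis=0)
        v_within += w * float(((g - mu_g) ** 2).sum() / g.shape[0])
        v_inter += w * float(((mu_g - mu) ** 2).sum())
    return v_inter, v_within, v_total


def select_axis_subset(space: ValidationSpace, max_axes: int = 10) -> EigenSubsetScore:
    """Exhaustive search over non-empty subsets of the leading ``max_axes``
    eigenvectors for the subset maximizing V_inter / Σ V_within on the
    learning samples; ties favour fewer axes, then lexicographic order."""
    m = min(max_axes, space.n_axes)
    if m < 1:
        raise DataError("no candidate axes")
    coords = space.learning_coords
    best: EigenSubsetScore | None = None
    for size in range(1, m + 1):
        for subset in combinations(range(m), size):
            v_inter, v_within, _ = variance_decomposition(
                coords, space.learning_is_a, subset
            )
            score = EigenSubsetScore(subset, v_inter, v_within)
            if best is None or score.ratio > best.ratio + 1e-15:
                best = score
    assert best is not None
    logger.info(
        "select_axis_subset: axes %s (ratio %.4g)", best.axes, best.ratio
    )
    return best


def reclassify_with_subset(
    space: ValidationSpace,
    subset: EigenSubsetScore,
    unattributed: list[str],
    attributed: dict[str, str] | None = None,
    sd_multiplier: float = 1.0,
) -> dict[str, SampleDecision]:
    """Recompute RMS decisions over the selected subset for previously
    unattributed samples; warn if any previously attributed sample would
    change its group under the subset (it is expected not to)."""
    out: dict[str, SampleDecision] = {}
    for s in unattributed:
        out[s] = classify_testing(
            space, s, axes=list(subset.axes), sd_multiplier=sd_multiplier
        )
    if attributed:
        for s, prev in attributed.items():
            redo = classify_testing(
                space, s, axes=list(subset.axes), sd_multiplier=sd_multiplier
            )
            if redo.decision in (ATTRIBUTED_A, ATTRIBUTED_B) and redo.decision != prev:
                logger.warning(
                    "reclassify_with_subset: %s would flip %s -> %s on axes %s",
                    s, prev, redo.decision, subset.axes,
                )
    return out


def classify_all_testing(
    space: ValidationSpace,
    testing_ids: list[str],
    sd_multiplier: float = 1.0,
    max_axes_subset: int = 10,
) -> list[SampleDecision]:
    """Escalation path per testing sample: leading axes, then all axes, then
    the variance-ratio-selected subset.  Each sample is handled case by
    case; the learning geometry is fixed, so order cannot matter."""
    decisions: dict[str, SampleDecision] = {}
    pending: list[str] = []
    for s in testing_ids:
        d = classify_testing(space, s, sd_multiplier=sd_multiplier)
        decisions[s] = d
        if d.decision == UNATTRIBUTED:
            pending.append(s)
    if pending and space.n_axes > space.n_axes_default:
        all_axes = list(range(space.n_axes))
        still: list[str] = []
        for s in pending:
            d = classify_testing(space, s, axes=all_axes, sd_multiplier=sd_multiplier)
            if d.decision != UNATTRIBUTED:
                decisions[s] = d
            else:
                still.append(s)
        pending = still
    if pending:
        subset = select_axis_subset(space, max_axes=max_axes_subset)
        attributed = {
            s: d.decision
            for s, d in decisions.items()
            if d.decision in (ATTRIBUTED_A, ATTRIBUTED_B)
        }
        redo = reclassify_with_subset(
            space, subset, pending, attributed, sd_multiplier=sd_multiplier
        )
        for s, d in redo.items():
            if d.decision != UNATTRIBUTED:
                decisions[s] = d
    return [decisions[s] for s in testing_ids]


def report_from_decisions(
    decisions: list[SampleDecision],
    true_group: dict[str, str],
    groups: tuple[str, str],
    provenance: dict | None = None,
) -> ClassificationReport:
    """Tally per-group well / false / unclassified counts against the truth.

    ``attributed_A`` maps to ``groups[0]`` and ``attributed_B`` to
    ``groups[1]``; unattributed and rejected samples count as
    unclassified."""
    counts = {g: {"well": 0, "false": 0, "unclassified": 0} for g in groups}
    for d in decisions:
        truth = true_group[d.sample_id]
        if d.decision == ATTRIBUTED_A:
            predicted = groups[0]
        elif d.decision == ATTRIBUTED_B:
            predicted = groups[1]
        else:
            counts[truth]["unclassified"] += 1
            continue
        counts[truth]["well" if predicted == truth else "false"] += 1
    return ClassificationReport(
        groups=groups,
        decisions=decisions,
        counts=counts,
        provenance=provenance or {},
    )
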