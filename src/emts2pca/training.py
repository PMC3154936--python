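"""Internal cross-validation of training matrices.

Each 10-sample design, restricted to its candidate genes and row
centered/normalized, defines a training space: the Cartesian coordinate
system of the three leading eigenvectors of its sample covariance.  The
held-out learning samples ("training tumors") are projected into that space
with the design's own row statistics and classified by the RMS decision
rules.  A training matrix is validated when it classifies at least one
training tumor correctly and none incorrectly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .combinatorics import TenSampleDesign
from .data_model import (
    ATTRIBUTED_A,
    ATTRIBUTED_B,
    REJECTED,
    UNATTRIBUTED,
    DataError,
)

logger = logging.getLogger("emts2pca")

__all__ = [
    "PcaSpace",
    "TrainingMatrix",
    "RmsProfile",
    "build_training_space",
    "project_samples",
    "compute_rms",
    "build_rms_profile",
    "classify_by_rms",
    "validate_training_matrix",
    "continuation_check",
]


# ---------------------------------------------------------------------------
# PCA space (shared by training and validation stages)
# ---------------------------------------------------------------------------


@dataclass
class PcaSpace:
    """Eigenstructure of a genes x samples matrix and the sample coordinates.

    ``axes`` are gene-space eigenvectors (columns), sign-fixed so the
    largest-magnitude component of each is positive; ``coords`` holds the
    reference samples' coordinates (samples x axes); eigenvalues are sorted
    descending (population normalization, divisor = number of samples).
    """

    axes: np.ndarray          # genes x r
    eigenvalues: np.ndarray   # r, descending
    coords: np.ndarray        # samples x r
    singular_values: np.ndarray
    n_axes_default: int = 3

    def project(self, columns: np.ndarray) -> np.ndarray:
        """Project new sample columns (genes x m) onto the eigenvectors."""
        return columns.T @ self.axes


def build_pca_space(values: np.ndarray, n_axes_default: int = 3) -> PcaSpace:
    """Eigendecomposition of the sample covariance of ``values`` columns.

    Implemented through the SVD of the matrix (rows as variables, columns as
    observations), which yields the same eigenvectors with better numerical
    behaviour for genes >> samples.  Coordinates conserve the total sum of
    squares of the input.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise DataError("need at least 2 gene rows to build a space")
    u, s, vt = np.linalg.svd(values, full_matrices=False)
    # deterministic sign: largest-|component| entry of each eigenvector > 0
    for k in range(u.shape[1]):
        j = int(np.argmax(np.abs(u[:, k])))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    coords = (s[:, None] * vt).T              # samples x r
    eigenvalues = s**2 / values.shape[1]      # population covariance eigenvalues
    return PcaSpace(
        axes=u,
        eigenvalues=eigenvalues,
        coords=coords,
        singular_values=s,
        n_axes_default=n_axes_default,
    )


def build_training_space(
    train_values: np.ndarray, n_axes: int = 3
) -> PcaSpace:
    """Training space of a candidate-gene design matrix (centered/normalized
    rows).  Uses the three leading eigenvectors, or all when fewer exist."""
    space = build_pca_space(train_values, n_axes_default=n_axes)
    return space


def project_samples(space: PcaSpace, columns: np.ndarray) -> np.ndarray:
    return space.project(np.asarray(columns, dtype=float))


# ---------------------------------------------------------------------------
# RMS decision rules
# ---------------------------------------------------------------------------


def compute_rms(
    ref_coords: np.ndarray,
    ref_is_group: np.ndarray,
    query_coords: np.ndarray,
    axes: np.ndarray | list[int],
) -> float:
    """Root mean square distance of a query to a subgroup barycenter over an
    eigenvector subset.

    ``ref_coords`` is samples x axes for the reference samples;
    ``ref_is_group`` marks the subgroup whose barycenter is used.
    """
    axes = np.asarray(axes, dtype=int)
    if axes.size == 0:
        raise DataError("empty eigenvector subset")
    ref_is_group = np.asarray(ref_is_group, dtype=bool)
    if not ref_is_group.any():
        raise DataError("reference subgroup is empty")
    bary = ref_coords[np.ix_(ref_is_group, axes)].mean(axis=0)
    d = np.asarray(query_coords, dtype=float)[axes] - bary
    return float(np.sqrt(np.mean(d**2)))


@dataclass
class RmsProfile:
    """RMS distances of reference samples (matrix side) and one query
    (class side) to the two subgroup barycenters."""

    rms_a_matrix: np.ndarray   # per reference sample, to A barycenter
    rms_b_matrix: np.ndarray   # per reference sample, to B barycenter
    ref_is_a: np.ndarray       # bool per reference sample
    rms_a_class: float
    rms_b_class: float

    @property
    def sd_a(self) -> float:
        return float(np.std(self.rms_a_matrix[self.ref_is_a]))

    @property
    def sd_b(self) -> float:
        return float(np.std(self.rms_b_matrix[~self.ref_is_a]))


def build_rms_profile(
    ref_coords: np.ndarray,
    ref_is_a: np.ndarray,
    query_coords: np.ndarray,
    axes: np.ndarray | list[int],
) -> RmsProfile:
    ref_is_a = np.asarray(ref_is_a, dtype=bool)
    n = ref_coords.shape[0]
    rms_a = np.array(
        [compute_rms(ref_coords, ref_is_a, ref_coords[j], axes) for j in range(n)]
    )
    rms_b = np.array(
        [compute_rms(ref_coords, ~ref_is_a, ref_coords[j], axes) for j in range(n)]
    )
    return RmsProfile(
        rms_a_matrix=rms_a,
        rms_b_matrix=rms_b,
        ref_is_a=ref_is_a,
        rms_a_class=compute_rms(ref_coords, ref_is_a, query_coords, axes),
        rms_b_class=compute_rms(ref_coords, ~ref_is_a, query_coords, axes),
    )


def classify_by_rms(profile: RmsProfile, sd_multiplier: float = 1.0) -> str:
    """Attributed / unattributed / rejected decision from an RMS profile.

    Separability: if any reference sample lies farther from its own
    barycenter than some other-subgroup sample lies from that same
    barycenter, the subgroups interleave and the decision is ``rejected``.
    Otherwise the query is assigned to subgroup g when its class-side RMS is
    below the largest matrix-side RMS of g's own samples plus
    ``sd_multiplier`` standard deviations of those values; qualifying for
    both or neither subgroup leaves it ``unattributed``.
    """
    in_a = profile.ref_is_a
    max_a_own = profile.rms_a_matrix[in_a].max()
    max_b_own = profile.rms_b_matrix[~in_a].max()
    # interleaving check against the same barycenter
    if max_a_own > profile.rms_a_matrix[~in_a].min():
        return REJECTED
    if max_b_own > profile.rms_b_matrix[in_a].min():
        return REJECTED
    fits_a = profile.rms_a_class < max_a_own + sd_multiplier * profile.sd_a
    fits_b = profile.rms_b_class < max_b_own + sd_multiplier * profile.sd_b
    if fits_a and not fits_b:
        return ATTRIBUTED_A
    if fits_b and not fits_a:
        return ATTRIBUTED_B
    return UNATTRIBUTED


# ---------------------------------------------------------------------------
# Training-matrix validation
# ---------------------------------------------------------------------------


@dataclass
class TrainingMatrix:
    """A design restricted to its candidate genes, with validation status.

    ``c`` counts the training tumors the matrix classified correctly; a
    validated matrix has ``c >= 1`` and no misclassification.
    """

    design: TenSampleDesign
    gene_ids: list[str]
    values: np.ndarray                  # centered/normalized, genes x 10
    validated: bool = False
    c: int = 0
    decisions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.validated and self.c < 1:
            raise DataError("validated matrix must have c >= 1")


def validate_training_matrix(
    decisions: dict[str, str], true_group_is_a: dict[str, bool]
) -> tuple[bool, int]:
    """Validated iff >= 1 training tumor correct and none misclassified
    (unattributed and rejected decisions are neutral).  Returns
    ``(validated, c)`` with c the number classified correctly."""
    correct = 0
    wrong = 0
    for sample, decision in decisions.items():
        if decision == ATTRIBUTED_A:
            if true_group_is_a[sample]:
                correct += 1
            else:
                wrong += 1
        elif decision == ATTRIBUTED_B:
            if true_group_is_a[sample]:
                wrong += 1
            else:
                correct += 1
    return (correct >= 1 and wrong == 0), correct


def continuation_check(
    matrices: list[TrainingMatrix],
    learning_samples: list[str],
    true_group_is_a: dict[str, bool],
    threshold: float = 0.9,
) -> tuple[bool, dict[str, bool]]:
    """Proceed iff at least ``threshold`` of the learning samples are
    correctly classified by at least one validated matrix and none is
    misclassified by any validated matrix (the latter holds by construction
    of validation).  Returns the flag and per-sample coverage."""
    covered = {s: False for s in learning_samples}
    for tm in matrices:
        if not tm.validated:
            continue
        for sample, decision in tm.decisions.items():
            if sample not in covered:
                continue
            is_a = true_group_is_a[sample]
            if (decision == ATTRIBUTED_A and is_a) or (
                decision == ATTRIBUTED_B and not is_a
            ):
                covered[sample] = True
    frac = sum(covered.values()) / len(covered) if covered else 0.0
    ok = frac >= threshold
    if not ok:
        missing = sorted(s for s, c in covered.items() if not c)
        logger.warning(
            "continuation_check failed: %.0f%% coverage; uncovered: %s",
            100 * frac, missing,
        )
    return ok, covered


def cross_validate_design(
    design: TenSampleDesign,
    candidate_values: np.ndarray,
    candidate_gene_ids: list[str],
    heldout_raw: np.ndarray,
    heldout_ids: list[str],
    heldout_is_a: dict[str, bool],
    raw_design_values: np.ndarray,
    n_axes: int = 3,
    sd_multiplier: float = 1.0,
) -> TrainingMatrix:
    """Build the training space of one design and classify its held-out
    learning samples.

    ``candidate_values`` are the centered/normalized candidate rows over the
    10 design columns; ``heldout_raw`` and ``raw_design_values`` are the raw
    log-ratios of the same candidate genes over the held-out and design
    columns respectively (the held-out samples are transformed with the
    design's own row statistics, never refit).
    """
    from .data_model import center_normalize_rows

    tm = TrainingMatrix(
        design=design, gene_ids=list(candidate_gene_ids), values=candidate_values
    )
    if len(candidate_gene_ids) < 2:
        logger.debug(
            "design %s discarded: %d candidate genes (< 2)",
            design.sample_ids, len(candidate_gene_ids),
        )
        return tm

    space = build_training_space(candidate_values, n_axes=n_axes)
    r = space.coords.shape[1]
    axes = list(range(min(n_axes, r)))

    # design row statistics from the raw design columns
    _, means, modules = center_normalize_rows(raw_design_values, candidate_gene_ids)
    transformed, _, _ = center_normalize_rows(
        heldout_raw, candidate_gene_ids, stats=(means, modules)
    )
    coords_heldout = space.project(transformed)

    k = len(design.half_a.sample_ids)
    ref_is_a = np.array([True] * k + [False] * (candidate_values.shape[1] - k))
    decisions: dict[str, str] = {}
    for i, sample in enumerate(heldout_ids):
        prof = build_rms_profile(space.coords, ref_is_a, coords_heldout[i], axes)
        decisions[sample] = classify_by_rms(prof, sd_multiplier=sd_multiplier)
    validated, c = validate_training_matrix(decisions, heldout_is_a)
    tm.validated = validated
    tm.c = c
    tm.decisions = decisions
    return tm
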