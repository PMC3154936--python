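"""End-to-end pipeline: learning, training, signature search, prediction.

The analytic stages are fully deterministic (fixed EM initialization,
lexicographic enumeration orders, eigenvector sign conventions); the single
seed in the configuration governs only synthetic-data generation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from . import __version__
from .combinatorics import (
    build_designs,
    enumerate_half_matrices,
    filter_confounder,
    filter_overlap,
)
from .data_model import (
    ClassificationReport,
    DataError,
    ExpressionMatrix,
    LEARNING,
    SampleMetadata,
    Signature,
    TESTING,
)
from .gene_screen import screen_design
from .prediction import (
    build_validation_space,
    classify_all_testing,
    report_from_decisions,
)
from .signature import (
    StandardizedMatrix,
    build_signature,
    compile_relevance,
    select_signature,
    standardize,
)
from .training import TrainingMatrix, continuation_check, cross_validate_design

logger = logging.getLogger("emts2pca")

__all__ = ["PipelineConfig", "EmtsResult", "run_emts", "run_predict", "run_all"]


@dataclass
class PipelineConfig:
    """All tunable knobs of the pipeline with their defaults."""

    half_size: int = 5
    max_shared_samples: int | None = None    # default floor(half_size / 2)
    t_filter_alpha: float = 0.05
    em_delta: float = 0.05
    em_max_iter: int = 20000
    em_tol: float = 1e-8
    n_axes_training: int = 3
    n_axes_validation: int = 3
    rms_sd_multiplier: float = 1.0
    continuation_threshold: float = 0.9
    relevance_normalization: str = "total_weight"
    relevance_marginal: str = "f_j"
    max_axes_subset_search: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def provenance(self) -> dict:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return {
            "config": self.to_dict(),
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "emts2pca_version": __version__,
            "numpy_version": np.__version__,
        }


@dataclass
class EmtsResult:
    """Outcome of the signature-search stage."""

    signature: Signature
    standardized: StandardizedMatrix
    matrices: list[TrainingMatrix]
    n_designs: int
    n_validated: int
    coverage: dict[str, bool]
    log: dict = field(default_factory=dict)


class ContinuationError(RuntimeError):
    """Internal cross-validation failed to cover enough learning samples."""

    def __init__(self, coverage: dict[str, bool], threshold: float):
        frac = sum(coverage.values()) / len(coverage) if coverage else 0.0
        missing = sorted(s for s, ok in coverage.items() if not ok)
        super().__init__(
            f"continuation check failed: {frac:.0%} of learning samples "
            f"covered (threshold {threshold:.0%}); uncovered: {missing}"
        )
        self.coverage = coverage


def run_emts(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    config: PipelineConfig | None = None,
) -> EmtsResult:
    """Learning, training with internal cross-validation, and signature
    search.  Raises ``ContinuationError`` when the validated matrices fail
    to cover the learning set."""
    config = config or PipelineConfig()
    meta.check_covers(matrix)
    group_a, group_b = meta.groups
    learn_a = meta.samples(group=group_a, split=LEARNING)
    learn_b = meta.samples(group=group_b, split=LEARNING)
    learning = learn_a + learn_b
    is_a = {s: (meta.group_of(s) == group_a) for s in learning}

    halves_a = filter_overlap(
        filter_confounder(
            enumerate_half_matrices(group_a, learn_a, k=config.half_size), meta
        ),
        config.max_shared_samples,
    )
    halves_b = filter_overlap(
        filter_confounder(
            enumerate_half_matrices(group_b, learn_b, k=config.half_size), meta
        ),
        config.max_shared_samples,
    )
    designs = build_designs(halves_a, halves_b, learning_samples=learning)

    matrices: list[TrainingMatrix] = []
    for design in designs:
        cols = matrix.sample_indexer(list(design.sample_ids))
        values = matrix.values[:, cols]
        k = len(design.half_a.sample_ids)
        group_mask = np.array([True] * k + [False] * (len(cols) - k))
        cands, cand_values = screen_design(
            values,
            matrix.gene_ids,
            group_mask,
            alpha=config.t_filter_alpha,
            delta=config.em_delta,
            max_iter=config.em_max_iter,
            tol=config.em_tol,
            design=design,
        )
        heldout = [s for s in learning if s not in set(design.sample_ids)]
        if len(cands.gene_ids) < 2:
            matrices.append(
                TrainingMatrix(design=design, gene_ids=cands.gene_ids,
                               values=cand_values)
            )
            continue
        rows = matrix.gene_indexer(cands.gene_ids)
        raw_design = matrix.values[np.ix_(rows, cols)]
        heldout_raw = matrix.values[np.ix_(rows, matrix.sample_indexer(heldout))]
        tm = cross_validate_design(
            design,
            cand_values,
            cands.gene_ids,
            heldout_raw,
            heldout,
            {s: is_a[s] for s in heldout},
            raw_design,
            n_axes=config.n_axes_training,
            sd_multiplier=config.rms_sd_multiplier,
        )
        matrices.append(tm)

    n_validated = sum(m.validated for m in matrices)
    logger.info("run_emts: %d/%d training matrices validated", n_validated, len(matrices))
    ok, coverage = continuation_check(
        matrices, learning, is_a, threshold=config.continuation_threshold
    )
    if not ok:
        raise ContinuationError(coverage, config.continuation_threshold)

    table = compile_relevance(
        matrices,
        learning,
        normalization=config.relevance_normalization,
        marginal_source=config.relevance_marginal,
    )
    sig_genes = select_signature(table)
    all_samples = learning + meta.samples(split=TESTING)
    all_samples = [s for s in all_samples if s in set(matrix.sample_ids)]
    std = standardize(matrices, matrix, sig_genes, all_samples, learning)
    signature = build_signature(table, std, is_a)
    return EmtsResult(
        signature=signature,
        standardized=std,
        matrices=matrices,
        n_designs=len(designs),
        n_validated=n_validated,
        coverage=coverage,
        log={
            "n_designs": len(designs),
            "n_validated": n_validated,
            "n_candidate_genes_total": table.n_genes,
            "signature_size": len(sig_genes),
        },
    )


def run_predict(
    std: StandardizedMatrix,
    meta: SampleMetadata,
    config: PipelineConfig | None = None,
) -> ClassificationReport:
    """Build the validation space from ξ′ and classify every testing sample
    case by case with the axis-escalation path."""
    config = config or PipelineConfig()
    group_a, group_b = meta.groups
    is_a = {s: (meta.group_of(s) == group_a) for s in std.learning_ids}
    space = build_validation_space(
        std, is_a, groups=(group_a, group_b),
        n_axes_default=config.n_axes_validation,
    )
    testing = [s for s in std.sample_ids if s not in set(std.learning_ids)]
    decisions = classify_all_testing(
        space,
        testing,
        sd_multiplier=config.rms_sd_multiplier,
        max_axes_subset=config.max_axes_subset_search,
    )
    truth = {s: meta.group_of(s) for s in testing}
    return report_from_decisions(
        decisions, truth, (group_a, group_b), provenance=config.provenance()
    )


def run_all(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    config: PipelineConfig | None = None,
) -> tuple[EmtsResult, ClassificationReport]:
    result = run_emts(matrix, meta, config)
    report = run_predict(result.standardized, meta, config)
    return result, report
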