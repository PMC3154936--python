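"""Compilation of validated training matrices into the final signature.

The frequency of relevance F(i,j) measures how often gene i and learning
sample j co-occur in a validated training matrix, weighted by the number
c(h) of training tumors matrix h classified correctly.  Genes whose row
mean F(i) reaches mF + 2 vF (statistics of the per-sample marginal F(j))
form the final signature.  The standardized matrix ξ averages, over the
validated matrices containing each signature gene, the design-standardized
expression of that gene extended to every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import DataError, ExpressionMatrix, Signature, center_normalize_rows
from .training import TrainingMatrix

logger = logging.getLogger("emts2pca")

__all__ = [
    "RelevanceTable",
    "StandardizedMatrix",
    "compile_relevance",
    "select_signature",
    "standardize",
]

TOTAL_WEIGHT = "total_weight"
TUMOR_WEIGHT = "tumor_weight"


@dataclass
class RelevanceTable:
    """F(i,j) over candidate genes x learning samples with its marginals.

    ``f_i`` is the per-gene row mean, ``f_j`` the per-sample column mean
    over all N candidate genes; ``m_f`` and ``v_f`` are the mean and
    (population) standard deviation of the column marginals F(j).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    f: np.ndarray
    h: int   # validated matrices compiled
    marginal_source: str = "f_j"  # statistics for the threshold: f_j (printed form) or f_i

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("relevance matrix shape mismatch")
        if np.any((self.f < 0) | (self.f > 1 + 1e-12)):
            raise DataError("F(i,j) must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def p(self) -> int:
        return len(self.sample_ids)

    @property
    def f_i(self) -> np.ndarray:
        return self.f.mean(axis=1)

    @property
    def f_j(self) -> np.ndarray:
        return self.f.mean(axis=0)

    @property
    def m_f(self) -> float:
        src = self.f_j if self.marginal_source == "f_j" else self.f_i
        return float(src.mean())

    @property
    def v_f(self) -> float:
        src = self.f_j if self.marginal_source == "f_j" else self.f_i
        return float(src.std())

    @property
    def threshold(self) -> float:
        return self.m_f + 2.0 * self.v_f


def compile_relevance(
    matrices: list[TrainingMatrix],
    learning_samples: list[str],
    normalization: str = TOTAL_WEIGHT,
    marginal_source: str = "f_j",
) -> RelevanceTable:
    """Compile validated matrices into the relevance table.

    ``F(i,j) = sum_h g(i_h, j_h) c(h) / W`` where ``g(i_h, j_h) = 1`` iff
    validated matrix h contains both gene i and sample j.  With the default
    ``total_weight`` normalization ``W = sum_h c(h)``; the ``tumor_weight``
    alternative uses ``W(j) = sum_h g(j_h) c(h)``, the weight of the
    matrices that contain sample j.
    """
    validated = [m for m in matrices if m.validated]
    if not validated:
        raise DataError("no validated training matrices")
    genes = sorted({g for m in validated for g in m.gene_ids})
    gene_idx = {g: i for i, g in enumerate(genes)}
    samp_idx = {s: j for j, s in enumerate(learning_samples)}

    num = np.zeros((len(genes), len(learning_samples)))
    tumor_w = np.zeros(len(learning_samples))
    total_w = 0.0
    for m in validated:
        c = float(m.c)
        total_w += c
        cols = [samp_idx[s] for s in m.design.sample_ids if s in samp_idx]
        rows = [gene_idx[g] for g in m.gene_ids]
        num[np.ix_(rows, cols)] += c
        tumor_w[cols] += c
    if normalization == TOTAL_WEIGHT:
        f = num / total_w
    elif normalization == TUMOR_WEIGHT:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(tumor_w[None, :] > 0, num / tumor_w[None, :], 0.0)
    else:
        raise DataError(f"unknown relevance normalization {normalization!r}")
    logger.info(
        "compile_relevance: H=%d validated matrices, N=%d candidate genes",
        len(validated), len(genes),
    )
    return RelevanceTable(
        gene_ids=genes,
        sample_ids=list(learning_samples),
        f=f,
        h=len(validated),
        marginal_source=marginal_source,
    )


def select_signature(table: RelevanceTable) -> list[str]:
    """Genes with ``F(i) >= mF + 2 vF`` (inclusive), in descending F(i)
    order; ties broken by gene id for determinism."""
    f_i = table.f_i
    thr = table.threshold
    chosen = [
        (f, g) for f, g in zip(f_i, table.gene_ids) if f >= thr
    ]
    if not chosen:
        raise DataError(
            "empty signature: no gene reached the relevance threshold "
            f"{thr:.4g} (F_i range {f_i.min():.4g}..{f_i.max():.4g}, "
            f"mF={table.m_f:.4g}, vF={table.v_f:.4g})"
        )
    chosen.sort(key=lambda t: (-t[0], t[1]))
    return [g for _, g in chosen]


@dataclass
class StandardizedMatrix:
    """ξ: signature genes x all samples, averaged design-standardized
    expression; ``provenance`` counts the matrices averaged per gene."""

    gene_ids: list[str]
    sample_ids: list[str]          # learning first, then testing
    learning_ids: list[str]
    values: np.ndarray
    provenance: np.ndarray         # per gene, number of contributing matrices

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError("standardized matrix shape mismatch")
        if np.any(self.provenance < 1):
            raise DataError("every ξ row must average >= 1 training matrix")

    @property
    def xi_prime(self) -> np.ndarray:
        """Restriction of ξ to the learning samples (columns)."""
        idx = [self.sample_ids.index(s) for s in self.learning_ids]
        return self.values[:, idx]


def standardize(
    matrices: list[TrainingMatrix],
    full_matrix: ExpressionMatrix,
    signature_genes: list[str],
    all_sample_ids: list[str],
    learning_ids: list[str],
) -> StandardizedMatrix:
    """Build ξ over ``all_sample_ids`` (the L learning + testing samples).

    For each validated matrix h: row means and modules are computed on the
    design columns only, each candidate-gene row is extended to all L
    samples and transformed with those design statistics (E_h); ξ(i,j) is
    the mean of E_h(i,j) over the validated matrices containing gene i.
    """
    validated = [m for m in matrices if m.validated]
    if not validated:
        raise DataError("no validated training matrices")
    missing = [g for g in signature_genes if g not in set(full_matrix.gene_ids)]
    if missing:
        raise DataError(f"signature genes absent from expression matrix: {missing}")
    sig_set = set(signature_genes)
    covered = {g for m in validated for g in m.gene_ids}
    uncovered = sorted(sig_set - covered)
    if uncovered:
        raise DataError(
            f"signature genes in no validated training matrix: {uncovered}"
        )

    gene_pos = {g: i for i, g in enumerate(signature_genes)}
    col_idx = full_matrix.sample_indexer(all_sample_ids)
    acc = np.zeros((len(signature_genes), len(all_sample_ids)))
    count = np.zeros(len(signature_genes))
    for m in validated:
        genes_h = [g for g in m.gene_ids if g in sig_set]
        if not genes_h:
            continue
        rows = full_matrix.gene_indexer(genes_h)
        design_cols = full_matrix.sample_indexer(list(m.design.sample_ids))
        raw_design = full_matrix.values[np.ix_(rows, design_cols)]
        _, means, modules = center_normalize_rows(raw_design, genes_h)
        extended = full_matrix.values[np.ix_(rows, col_idx)]
        e_h, _, _ = center_normalize_rows(extended, genes_h, stats=(means, modules))
        pos = [gene_pos[g] for g in genes_h]
        acc[pos] += e_h
        count[np.asarray(pos)] += 1
    values = acc / count[:, None]
    return StandardizedMatrix(
        gene_ids=list(signature_genes),
        sample_ids=list(all_sample_ids),
        learning_ids=list(learning_ids),
        values=values,
        provenance=count.astype(int),
    )


def signature_differential(
    std: StandardizedMatrix, learning_is_a: dict[str, bool]
) -> np.ndarray:
    """Per-gene mean difference (group A minus group B) of ξ over the
    learning samples — the reported differential value of the signature."""
    idx = [std.sample_ids.index(s) for s in std.learning_ids]
    is_a = np.array([learning_is_a[s] for s in std.learning_ids])
    sub = std.values[:, idx]
    return sub[:, is_a].mean(axis=1) - sub[:, ~is_a].mean(axis=1)


def build_signature(
    table: RelevanceTable,
    std: StandardizedMatrix,
    learning_is_a: dict[str, bool],
) -> Signature:
    f_map = dict(zip(table.gene_ids, table.f_i))
    diffs = signature_differential(std, learning_is_a)
    return Signature(
        gene_ids=list(std.gene_ids),
        f_i=np.array([f_map[g] for g in std.gene_ids]),
        diff=diffs,
    )
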