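"""Synthetic two-group expression series with planted signatures.

The generator emulates the statistical structure the signature search
assumes: two subgroups sharing a set of oppositely regulated signature
genes, per-tumor heterogeneity in which a fraction of signature entries are
replaced by background noise, a binary confounder (etiology) driving its own
gene set, and a large background of null genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    LEARNING,
    TESTING,
    DataError,
    ExpressionMatrix,
    SampleMetadata,
)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "assign_etiologies"]

GROUP_A = "A"
GROUP_B = "B"


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults are the strong-signal design used throughout testing: 2000
    genes of which 50 carry the signature, a signature effect of three noise
    standard deviations in mean absolute log-ratio, 20% per-entry
    heterogeneity, and 13+13 learning / 14+14 testing samples.
    """

    n_genes: int = 2000
    n_signature: int = 50
    n_confounder_genes: int = 30
    n_learning_per_group: int = 13
    n_testing_per_group: int = 14
    effect: float = 0.9            # mean |log-ratio| of signature genes
    heterogeneity: float = 0.2     # per-entry replacement probability
    noise_sd: float = 0.3
    confounder_effect: float = 0.9
    confounder_fraction: float = 0.5
    heavy_tailed: bool = False     # Student-t noise (df=3) instead of Gaussian
    seed: int = 0

    def validate(self) -> None:
        if self.n_signature + self.n_confounder_genes > self.n_genes:
            raise DataError("n_signature + n_confounder_genes exceeds n_genes")
        for name in (
            "n_genes",
            "n_signature",
            "n_learning_per_group",
            "n_testing_per_group",
        ):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.n_confounder_genes < 0:
            raise DataError("n_confounder_genes must be >= 0")
        if not (0 <= self.heterogeneity < 1):
            raise DataError("heterogeneity must lie in [0, 1)")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if not (0 < self.confounder_fraction < 1):
            raise DataError("confounder_fraction must lie in (0, 1)")


@dataclass
class SimulationTruth:
    """Planted structure: signature gene ids with per-gene direction
    (+1 means up in group A), and the confounder gene ids."""

    signature_genes: list[str]
    directions: dict[str, int]
    confounder_genes: list[str] = field(default_factory=list)


def _noise(rng: np.random.Generator, shape, sd: float, heavy: bool) -> np.ndarray:
    if heavy:
        # t(3) scaled to the requested standard deviation
        return rng.standard_t(3, size=shape) * sd / np.sqrt(3.0)
    return rng.normal(0.0, sd, size=shape)


def simulate(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, SimulationTruth]:
    """Generate an expression matrix, metadata and the planted truth.

    Signature genes have mean ``+effect`` in one group and ``-effect`` in the
    other (direction fixed per gene); each signature entry is independently
    replaced by pure background noise with probability ``heterogeneity``.
    Confounder genes depend only on the per-sample etiology label.
    Background genes are noise with mean zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_l, n_t = config.n_learning_per_group, config.n_testing_per_group
    sample_ids: list[str] = []
    groups: list[str] = []
    splits: list[str] = []
    for grp, n, split, tag in (
        (GROUP_A, n_l, LEARNING, "L"),
        (GROUP_B, n_l, LEARNING, "L"),
        (GROUP_A, n_t, TESTING, "T"),
        (GROUP_B, n_t, TESTING, "T"),
    ):
        for i in range(n):
            sample_ids.append(f"{tag}{grp}{i + 1:02d}")
            groups.append(grp)
            splits.append(split)
    n_samples = len(sample_ids)
    group_arr = np.asarray(groups)

    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    sig_genes = gene_ids[: config.n_signature]
    conf_genes = gene_ids[config.n_signature : config.n_signature + config.n_confounder_genes]

    values = _noise(rng, (config.n_genes, n_samples), config.noise_sd, config.heavy_tailed)

    # planted signature: per-gene orientation, per-entry dropout to noise
    directions = rng.choice([1, -1], size=config.n_signature)
    sign_by_sample = np.where(group_arr == GROUP_A, 1.0, -1.0)
    mean_block = directions[:, None] * sign_by_sample[None, :] * config.effect
    keep = rng.random((config.n_signature, n_samples)) >= config.heterogeneity
    values[: config.n_signature] += np.where(keep, mean_block, 0.0)

    meta_table = pd.DataFrame(
        {"group": groups, "split": splits}, index=pd.Index(sample_ids, name="sample_id")
    )
    meta = SampleMetadata(meta_table)
    meta = assign_etiologies(
        meta,
        {GROUP_A: config.confounder_fraction, GROUP_B: config.confounder_fraction},
        seed=int(rng.integers(2**31 - 1)),
    )

    # confounder genes track etiology only
    if conf_genes:
        conf = meta.table["confounder"].to_numpy()
        conf_sign = np.where(conf == "radiation", 1.0, -1.0)
        conf_dir = rng.choice([1, -1], size=len(conf_genes))
        values[
            config.n_signature : config.n_signature + len(conf_genes)
        ] += conf_dir[:, None] * conf_sign[None, :] * config.confounder_effect

    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = SimulationTruth(
        signature_genes=list(sig_genes),
        directions={g: int(d) for g, d in zip(sig_genes, directions)},
        confounder_genes=list(conf_genes),
    )
    return matrix, meta, truth


def assign_etiologies(
    meta: SampleMetadata,
    fractions: dict[str, float],
    seed: int = 0,
) -> SampleMetadata:
    """Assign a binary confounder label ("sporadic"/"radiation") per sample.

    Within each subgroup, a fraction of samples (rounded, but at least one
    of each level) is labelled "radiation"; both levels must be realizable,
    otherwise an error is raised so the within-group etiology filter stays
    exercisable downstream.
    """
    rng = np.random.default_rng(seed)
    labels = pd.Series("sporadic", index=meta.table.index, dtype=object)
    for grp, frac in fractions.items():
        if not (0 < frac < 1):
            raise DataError(f"fraction for group {grp!r} must lie in (0, 1)")
        ids = meta.samples(group=grp)
        n = len(ids)
        n_rad = int(round(frac * n))
        if n < 2 or n_rad == 0 or n_rad == n:
            raise DataError(
                f"group {grp!r} too small (n={n}) for both etiology levels at "
                f"fraction {frac}"
            )
        chosen = rng.choice(np.asarray(ids, dtype=object), size=n_rad, replace=False)
        labels.loc[list(chosen)] = "radiation"
    table = meta.table.copy()
    table["confounder"] = labels
    return SampleMetadata(table)
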