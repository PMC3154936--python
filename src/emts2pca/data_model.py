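"""Core containers and I/O for two-group expression series.

Expression values are normalized log expression ratios arranged genes x
samples.  Sample metadata carries the two-subgroup label (e.g. benign vs
malignant histology), an optional binary confounder such as etiology
(sporadic vs radiation-induced), and the learning/testing split used by the
signature search.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("emts2pca")

LEARNING = "learning"
TESTING = "testing"

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "Signature",
    "SampleDecision",
    "ClassificationReport",
    "read_expression",
    "read_metadata",
    "write_metadata",
    "read_signature",
    "write_signature",
    "read_report",
    "write_report",
    "center_normalize_rows",
]


class DataError(ValueError):
    """Raised when an input file or container violates an invariant."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log expression ratios.

    Parameters
    ----------
    gene_ids : sequence of unique gene identifiers (rows).
    sample_ids : sequence of unique sample identifiers (columns).
    values : float array of shape ``(len(gene_ids), len(sample_ids))`` with
        every entry finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise DataError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise DataError(f"duplicate sample ids: {sorted(dup_s)}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values must all be finite")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_indexer(self, gene_ids: Sequence[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self._gene_index]
        if missing:
            raise DataError(f"genes absent from matrix: {missing}")
        return np.asarray([self._gene_index[g] for g in gene_ids], dtype=int)

    def sample_indexer(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self._sample_index]
        if missing:
            raise DataError(f"samples absent from matrix: {missing}")
        return np.asarray([self._sample_index[s] for s in sample_ids], dtype=int)

    def subset(
        self,
        gene_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        genes = list(gene_ids) if gene_ids is not None else self.gene_ids
        samples = list(sample_ids) if sample_ids is not None else self.sample_ids
        sub = self.values[np.ix_(self.gene_indexer(genes), self.sample_indexer(samples))]
        return ExpressionMatrix(genes, samples, sub)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in ids:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (gene id column + sample header).

    Rows containing any non-numeric or missing entry are dropped and counted
    in the log; duplicate gene or sample ids raise an error naming the
    offenders.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    if df.empty and df.shape[1] == 0:
        raise DataError(f"{path}: empty expression file")
    dup_s = _duplicates(df.columns)
    if dup_s:
        raise DataError(f"{path}: duplicate sample ids: {sorted(dup_s)}")
    dup_g = _duplicates(df.index.astype(str))
    if dup_g:
        raise DataError(f"{path}: duplicate gene ids: {sorted(dup_g)}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "read_expression: dropped %d/%d rows with missing or non-numeric "
            "values", n_dropped, len(df)
        )
    numeric = numeric.loc[keep]
    if numeric.empty:
        raise DataError(f"{path}: no usable rows after dropping missing values")
    return ExpressionMatrix(
        [str(g) for g in numeric.index], [str(c) for c in numeric.columns],
        numeric.to_numpy(dtype=float),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")  # default repr round-trips doubles exactly


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample annotation: subgroup, optional confounder, and split.

    ``groups`` is the ordered pair of subgroup labels (deterministically the
    sorted distinct labels) used everywhere downstream as (A, B).
    """

    table: pd.DataFrame  # index: sample_id; columns: group, confounder?, split

    def __post_init__(self) -> None:
        t = self.table
        if "group" not in t.columns or "split" not in t.columns:
            raise DataError("metadata requires 'group' and 'split' columns")
        dup = _duplicates(t.index.astype(str))
        if dup:
            raise DataError(f"duplicate sample ids in metadata: {sorted(dup)}")
        bad_split = set(t["split"]) - {LEARNING, TESTING}
        if bad_split:
            raise DataError(f"unknown split labels: {sorted(bad_split)}")
        labels = sorted(set(t["group"].astype(str)))
        if len(labels) != 2:
            raise DataError(f"exactly two subgroup labels required, got {labels}")
        self.groups: tuple[str, str] = (labels[0], labels[1])
        for g in labels:
            if not ((t["group"].astype(str) == g) & (t["split"] == LEARNING)).any():
                raise DataError(f"learning split has no samples of group {g!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.table.index]

    @property
    def has_confounder(self) -> bool:
        return "confounder" in self.table.columns and self.table["confounder"].notna().all()

    def group_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "group"])

    def confounder_of(self, sample_id: str) -> str | None:
        if not self.has_confounder:
            return None
        return str(self.table.loc[sample_id, "confounder"])

    def samples(self, group: str | None = None, split: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if group is not None:
            mask &= self.table["group"].astype(str) == group
        if split is not None:
            mask &= self.table["split"] == split
        return [str(s) for s in self.table.index[mask]]

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise DataError(f"samples without metadata: {missing}")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: metadata requires a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------


@dataclass
class Signature:
    """Final gene signature: ids, relevance frequency F_i, and the mean
    log-ratio difference between groups in the validation data."""

    gene_ids: list[str]
    f_i: np.ndarray
    diff: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.f_i = np.asarray(self.f_i, dtype=float)
        self.diff = np.asarray(self.diff, dtype=float)
        if _duplicates(self.gene_ids):
            raise DataError("duplicate gene ids in signature")
        if not (len(self.gene_ids) == len(self.f_i) == len(self.diff)):
            raise DataError("signature fields must have equal length")
        if np.any((self.f_i < 0) | (self.f_i > 1)):
            raise DataError("F_i values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.gene_ids)


def write_signature(sig: Signature, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": sig.gene_ids, "F_i": sig.f_i, "diff": sig.diff}
    ).to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path) -> Signature:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     float_precision="round_trip")
    return Signature(list(df["gene_id"]), df["F_i"].to_numpy(), df["diff"].to_numpy())


# ---------------------------------------------------------------------------
# Classification report
# ---------------------------------------------------------------------------

ATTRIBUTED_A = "attributed_A"
ATTRIBUTED_B = "attributed_B"
UNATTRIBUTED = "unattributed"
REJECTED = "rejected"


@dataclass
class SampleDecision:
    """Decision for one classified sample with its two RMS distances."""

    sample_id: str
    decision: str  # attributed to a concrete group label, or "unattributed"/"rejected"
    rms_a: float
    rms_b: float
    axes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "decision": self.decision,
            "rms_a": self.rms_a,
            "rms_b": self.rms_b,
            "axes": list(self.axes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleDecision":
        return cls(
            sample_id=str(d["sample_id"]),
            decision=str(d["decision"]),
            rms_a=float(d["rms_a"]),
            rms_b=float(d["rms_b"]),
            axes=[int(a) for a in d.get("axes", [])],
        )


@dataclass
class ClassificationReport:
    """Per-sample decisions plus per-group well / false / unclassified counts.

    ``counts`` maps each true-group label to ``{"well": w, "false": f,
    "unclassified": u}`` following the three-category scoring (correct,
    misclassified, unattributed-or-rejected).
    """

    groups: tuple[str, str]
    decisions: list[SampleDecision]
    counts: dict[str, dict[str, int]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(sum(c.values()) for c in self.counts.values())
        if total != len(self.decisions):
            raise DataError(
                f"counts total {total} != {len(self.decisions)} decisions"
            )

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "decisions": [d.to_dict() for d in self.decisions],
            "counts": self.counts,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassificationReport":
        return cls(
            groups=tuple(d["groups"]),
            decisions=[SampleDecision.from_dict(x) for x in d["decisions"]],
            counts={
                g: {k: int(v) for k, v in c.items()} for g, c in d["counts"].items()
            },
            provenance=dict(d.get("provenance", {})),
        )


def write_report(report: ClassificationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))


def read_report(path: str | Path) -> ClassificationReport:
    return ClassificationReport.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Row centering / normalization
# ---------------------------------------------------------------------------


def center_normalize_rows(
    values: np.ndarray,
    gene_ids: Sequence[str] | None = None,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each row to mean 0 and scale to unit Euclidean norm (module).

    When ``stats=(means, modules)`` is supplied, the transform
    ``(x - m) / M`` is applied with those externally fixed statistics
    instead (rows then need not end up with zero mean); this is how samples
    outside a training design are placed on the design's own scale.

    Returns ``(transformed, means, modules)``.  A row whose module is zero
    (constant row) raises an error naming the gene.
    """
    values = np.asarray(values, dtype=float)
    if stats is None:
        means = values.mean(axis=1)
        centered = values - means[:, None]
        modules = np.linalg.norm(centered, axis=1)
        bad = np.nonzero(modules == 0)[0]
        if bad.size:
            names = (
                [gene_ids[i] for i in bad] if gene_ids is not None else bad.tolist()
            )
            raise DataError(f"zero module (constant row) for genes: {names}")
        return centered / modules[:, None], means, modules
    means, modules = (np.asarray(a, dtype=float) for a in stats)
    bad = np.nonzero(modules == 0)[0]
    if bad.size:
        names = [gene_ids[i] for i in bad] if gene_ids is not None else bad.tolist()
        raise DataError(f"zero module supplied for genes: {names}")
    return (values - means[:, None]) / modules[:, None], means, modules
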