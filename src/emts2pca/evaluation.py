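"""Three-category prediction scoring.

The classifier outputs three categories per sample — correctly classified,
misclassified, and unclassified — so the usual dichotomous evaluators are
complemented by the relative predictive efficiency RPE (correct / predicted)
and the general predictive efficiency GPE (correct / all samples).
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_model import ClassificationReport, DataError

__all__ = [
    "PredictionCounts",
    "rpe",
    "gpe",
    "sensitivity_specificity",
    "counts_from_report",
]

PER_GROUP = "per_group"
CORRECT_VS_REST = "correct_vs_rest"


@dataclass
class PredictionCounts:
    """Per-group well / false / unclassified tallies.

    ``per_group`` maps each group label to a dict with keys
    ``well``, ``false`` and ``unclassified``.
    """

    per_group: dict[str, dict[str, int]]

    def __post_init__(self) -> None:
        for g, c in self.per_group.items():
            for key in ("well", "false", "unclassified"):
                if c.get(key, 0) < 0:
                    raise DataError(f"negative count {key} for group {g!r}")

    def total(self, key: str) -> int:
        return sum(c.get(key, 0) for c in self.per_group.values())


def counts_from_report(report: ClassificationReport) -> PredictionCounts:
    return PredictionCounts(per_group={g: dict(c) for g, c in report.counts.items()})


def rpe(counts: PredictionCounts) -> float:
    """Relative predictive efficiency: pooled correct / pooled predicted
    (correctly plus incorrectly predicted)."""
    well = counts.total("well")
    false = counts.total("false")
    if well + false == 0:
        raise DataError("RPE undefined: no predicted samples")
    return well / (well + false)


def gpe(counts: PredictionCounts) -> float:
    """General predictive efficiency: pooled correct / all samples
    (correct, misclassified and unclassified)."""
    total = counts.total("well") + counts.total("false") + counts.total("unclassified")
    if total == 0:
        raise DataError("GPE undefined: no samples")
    return counts.total("well") / total


def sensitivity_specificity(
    counts: PredictionCounts,
    positive_group: str,
    dichotomization: str = CORRECT_VS_REST,
) -> tuple[float, float]:
    """Sensitivity and specificity after collapsing to two categories.

    ``correct_vs_rest`` (the published adaptation) calls a sample positive
    when it belongs to ``positive_group`` and the classifier got it right;
    misclassified and unclassified samples fall to the negative call.
    ``per_group`` instead treats any attribution to the positive group as a
    positive call (false calls of negative-group samples become false
    positives).
    """
    if positive_group not in counts.per_group:
        raise DataError(f"unknown positive group {positive_group!r}")
    pos = counts.per_group[positive_group]
    neg_groups = [c for g, c in counts.per_group.items() if g != positive_group]
    if sum(pos.values()) == 0:
        raise DataError("positive group has no samples")

    if dichotomization == CORRECT_VS_REST:
        tp = pos["well"]
        fn = pos["false"] + pos["unclassified"]
        # negative-group samples are true negatives when not called positive;
        # their misclassifications are attributions to the positive group
        fp = sum(c["false"] for c in neg_groups)
        tn = sum(c["well"] + c["unclassified"] for c in neg_groups)
    elif dichotomization == PER_GROUP:
        tp = pos["well"]
        fn = pos["false"] + pos["unclassified"]
        fp = sum(c["false"] for c in neg_groups)
        tn = sum(c["well"] + c["unclassified"] for c in neg_groups)
    else:
        raise DataError(f"unknown dichotomization {dichotomization!r}")

    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec
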