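"""Per-cytosine scoring of DMR calls against truth.

A region's Bayes factor is propagated to each member CpG; CpGs not covered by
any returned region get a score of zero.  Ranking quality is summarised by
AUROC (mid-rank tie handling) and average precision (tie-aware; its baseline
for an uninformative ranking equals the positive-class fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class ScoredCpgs:
    """Truth labels and propagated scores over the evaluation universe."""

    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int8)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores shapes differ")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0/1")

    @property
    def positive_fraction(self) -> float:
        return float(self.labels.mean())


def propagate_scores(
    results: Sequence,
    labels: np.ndarray,
    n_sites: int | None = None,
    transform: str = "identity",
) -> ScoredCpgs:
    """Spread each region's Bayes factor onto its member CpGs.

    ``results`` are :class:`~dmrseg.bayes.DMRResult` objects (or any object
    with ``region.site_indices`` and ``bayes_factor``).  CpGs outside every
    region score 0.  ``transform="log"`` uses log(BF) floored at 0, which
    preserves ranking among scored CpGs while keeping the zero convention.
    """
    labels = np.asarray(labels)
    n = n_sites if n_sites is not None else len(labels)
    if len(labels) != n:
        raise ValueError("labels length does not match universe size")
    if transform not in ("identity", "log"):
        raise ValueError(f"unknown transform '{transform}'")
    scores = np.zeros(n, dtype=float)
    for res in results:
        region = getattr(res, "region", res)
        bf = float(getattr(res, "bayes_factor"))
        idx = np.asarray(region.site_indices, dtype=np.int64)
        if idx.min(initial=0) < 0 or (len(idx) and idx.max() >= n):
            raise ValueError(
                f"region {region.chrom}:{region.start_pos}-{region.end_pos} "
                "references a CpG outside the evaluation universe")
        scores[idx] = np.log(bf).clip(min=0.0) if transform == "log" else bf
    return ScoredCpgs(labels=labels, scores=scores)


def auroc(scored: ScoredCpgs) -> float:
    """Area under the ROC curve with mid-rank handling of tied scores."""
    labels = scored.labels
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scored.scores))


def average_precision(scored: ScoredCpgs) -> float:
    """Tie-aware average precision (area under the precision-recall curve).

    Tied scores are treated as a single threshold block, so a constant score
    vector yields exactly the positive fraction — the chance baseline.
    """
    if scored.labels.sum() == 0:
        raise ValueError("average precision needs at least one positive")
    return float(average_precision_score(scored.labels, scored.scores))


def ranking_metrics(scored: ScoredCpgs) -> dict[str, float]:
    """AUROC, AP and the AP chance baseline in one dict."""
    return {
        "auroc": auroc(scored),
        "average_precision": average_precision(scored),
        "ap_baseline": scored.positive_fraction,
    }


def labels_from_intervals(
    positions: np.ndarray,
    chroms: np.ndarray,
    intervals: Sequence[tuple[str, int, int]],
) -> np.ndarray:
    """0/1 labels for CpGs falling inside 0-based half-open truth intervals."""
    positions = np.asarray(positions, dtype=np.int64)
    chroms = np.asarray(chroms)
    labels = np.zeros(len(positions), dtype=np.int8)
    for chrom, start, end in intervals:
        inside = (chroms == chrom) & (positions > start) & (positions <= end)
        labels[inside] = 1
    return labels


def scores_from_intervals(
    positions: np.ndarray,
    chroms: np.ndarray,
    scored_intervals: Sequence[tuple[str, int, int, float]],
) -> np.ndarray:
    """Propagate interval scores (e.g. read back from a BED) onto CpGs."""
    positions = np.asarray(positions, dtype=np.int64)
    chroms = np.asarray(chroms)
    scores = np.zeros(len(positions), dtype=float)
    for chrom, start, end, score in scored_intervals:
        inside = (chroms == chrom) & (positions > start) & (positions <= end)
        scores[inside] = score
    return scores
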