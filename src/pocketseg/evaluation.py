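"""Pocket-detection metrics: DCC, DVO, matching, success rate, F1.

DCC is the Euclidean distance between predicted and reference pocket
centers; a site is counted as correctly located when its DCC is below
4 Å.  DVO (discretized volume overlap) is the intersection-over-union of
the two segmentations on the voxel lattice.  For each structure only the
n highest-scoring predictions are considered (n = number of reference
pockets); each is matched to its closest reference pocket.  Reference
pockets left without any prediction receive the worst possible values:
DVO = 0 and DCC equal to the grid diagonal (121.24 Å for the default
70 Å lattice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .grid import GridSpec, PocketMask
from .inference import PocketSegment

DCC_SUCCESS_THRESHOLD = 4.0


@dataclass
class ReferencePocket:
    """A ground-truth pocket: its voxel mask and its center in Å.

    The center is the mean of the reference pocket points (or, lacking
    those, of the mask's voxel centers).
    """

    mask: PocketMask
    center: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    @classmethod
    def from_mask(cls, mask: PocketMask) -> "ReferencePocket":
        idx = np.argwhere(mask.values)
        if len(idx) == 0:
            raise ValueError("reference pocket mask is empty")
        return cls(mask, mask.spec.node_coords(idx).mean(axis=0))


@dataclass
class MatchResult:
    """One (prediction, reference) pairing, or a sentinel for a miss."""

    true_center: np.ndarray
    dcc: float
    dvo: float
    sentinel: bool
    predicted_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sentinel and (self.dvo != 0 or self.predicted_center is not None):
            raise ValueError("sentinel results must have dvo=0 and no predicted center")
        if self.dcc < 0 or not 0 <= self.dvo <= 1:
            raise ValueError("dcc must be >= 0 and dvo in [0, 1]")


def dcc(center_a: np.ndarray, center_b: np.ndarray) -> float:
    """Distance between pocket centers, Å."""
    return float(np.linalg.norm(np.asarray(center_a, float) - np.asarray(center_b, float)))


def sentinel_dcc(spec: GridSpec = GridSpec()) -> float:
    """Worst possible DCC on a lattice: its space diagonal, span·√3 Å."""
    return float(spec.span * np.sqrt(3.0))


def dvo(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Discretized volume overlap |A∩B| / |A∪B|; 0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_predictions(
    predicted: list[PocketSegment],
    truths: list[ReferencePocket],
    spec: GridSpec,
    exclusive: bool = False,
) -> list[MatchResult]:
    """Match top-n predictions to reference pockets and score them.

    Predictions are truncated to the n highest scores (n = number of
    reference pockets).  By default each retained prediction is matched to
    the reference pocket with the smallest DCC (non-exclusive: one
    reference may attract several predictions); ``exclusive=True`` solves
    the assignment problem instead, for sensitivity analysis.  Every
    reference pocket with no matched prediction yields a sentinel result
    with the worst possible metric values.
    """
    if not truths:
        raise ValueError("at least one reference pocket is required")
    retained = sorted(predicted, key=lambda s: -s.score)[: len(truths)]
    results: list[MatchResult] = []
    matched_truths: set[int] = set()
    if retained:
        dmat = np.array([[dcc(p.center, t.center) for t in truths] for p in retained])
        if exclusive:
            rows, cols = linear_sum_assignment(dmat)
            pairs = list(zip(rows.tolist(), cols.tolist()))
        else:
            pairs = [(i, int(np.argmin(dmat[i]))) for i in range(len(retained))]
        for i, j in pairs:
            seg, truth = retained[i], truths[j]
            matched_truths.add(j)
            results.append(
                MatchResult(
                    true_center=truth.center,
                    dcc=dmat[i, j],
                    dvo=dvo(seg.mask(), truth.mask.values),
                    sentinel=False,
                    predicted_center=seg.center,
                )
            )
    worst = sentinel_dcc(spec)
    for j, truth in enumerate(truths):
        if j not in matched_truths:
            results.append(
                MatchResult(true_center=truth.center, dcc=worst, dvo=0.0, sentinel=True)
            )
    return results


def success_rate(matches: list[MatchResult], threshold: float = DCC_SUCCESS_THRESHOLD) -> float:
    """Fraction of matches with DCC strictly below ``threshold`` Å."""
    if not matches:
        raise ValueError("no matches to evaluate")
    return sum(m.dcc < threshold for m in matches) / len(matches)


def success_rate_curve(
    matches: list[MatchResult],
    thresholds: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """(threshold, success rate) pairs; default thresholds 0–20 Å in 0.5 Å steps."""
    if thresholds is None:
        thresholds = np.arange(0.0, 20.5, 0.5)
    return [(float(t), success_rate(matches, float(t))) for t in thresholds]


def detection_f1(
    matches: list[MatchResult],
    n_predicted_total: int,
    n_truth_total: int,
    dcc_threshold: float = DCC_SUCCESS_THRESHOLD,
) -> tuple[float, float, float]:
    """Detection precision, recall and F1 at a DCC true-positive threshold.

    A true positive is a non-sentinel match with DCC below the threshold.
    Precision divides by the number of (retained) predictions, recall by
    the number of reference pockets; F1 is their harmonic mean (0 when
    both are 0).
    """
    tp = sum((not m.sentinel) and m.dcc < dcc_threshold for m in matches)
    precision = tp / n_predicted_total if n_predicted_total else 0.0
    recall = tp / n_truth_total if n_truth_total else 0.0
    f1 = f1_score(precision, recall)
    return precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalSummary:
    """Aggregate evaluation over a set of structures."""

    success_rate_curve: list[tuple[float, float]]
    precision: float
    recall: float
    f1: float
    n_structures_no_prediction: int
    n_matches: int = 0

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.success_rate_curve]
        if any(b < a - 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValueError("success-rate curve must be non-decreasing in threshold")


def summarize(
    per_structure: list[tuple[list[PocketSegment], list[ReferencePocket], list[MatchResult]]],
    dcc_threshold: float = DCC_SUCCESS_THRESHOLD,
) -> EvalSummary:
    """Pool per-structure match results into curve, F1 and miss counts."""
    all_matches: list[MatchResult] = []
    n_pred = n_truth = n_missed = 0
    for predicted, truths, matches in per_structure:
        all_matches.extend(matches)
        n_pred += min(len(predicted), len(truths))
        n_truth += len(truths)
        if not predicted:
            n_missed += 1
    precision, recall, f1 = detection_f1(all_matches, n_pred, n_truth, dcc_threshold)
    return EvalSummary(
        success_rate_curve=success_rate_curve(all_matches),
        precision=precision,
        recall=recall,
        f1=f1,
        n_structures_no_prediction=n_missed,
        n_matches=len(all_matches),
    )
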