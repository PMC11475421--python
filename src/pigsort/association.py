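"""Track/detection association: IoU + direction-consistency cost, Hungarian
assignment, and the second-stage recovery association for lost tracks.

The primary cost for track i and detection j is

    C[i, j] = -IoU(predicted box_i, detection box_j) + lambda * C_v(i, j)

where C_v penalizes the angular difference between the track's historical
motion direction and the direction implied by linking the track's
reference observation to the candidate detection (observation-centric
momentum). Cells whose IoU falls below a gate are infeasible and can
never be matched. Lost tracks get a second chance: their *last real
observed box* (not the drifting prediction) is matched against leftover
detections by IoU alone (observation-centric recovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "CostMatrix",
    "AssociationResult",
    "iou",
    "iou_matrix",
    "velocity_consistency_cost",
    "build_cost",
    "solve_assignment",
    "ocr_associate",
]


@dataclass
class CostMatrix:
    """N x M association costs with a feasibility mask (True = allowed)."""

    values: np.ndarray
    feasible: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feasible = np.asarray(self.feasible, dtype=bool)
        if self.values.shape != self.feasible.shape:
            raise ValueError("values and feasibility mask shapes differ")
        if not np.all(np.isfinite(self.values[self.feasible])):
            raise ValueError("non-finite cost on a feasible cell")


@dataclass(frozen=True)
class AssociationResult:
    matches: tuple[tuple[int, int], ...]
    unmatched_tracks: tuple[int, ...]
    unmatched_detections: tuple[int, ...]


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (left, top, width, height) boxes."""
    la, ta, wa, ha = box_a
    lb, tb, wb, hb = box_b
    ix = max(0.0, min(la + wa, lb + wb) - max(la, lb))
    iy = max(0.0, min(ta + ha, tb + hb) - max(ta, tb))
    inter = ix * iy
    union = wa * ha + wb * hb - inter
    return inter / union if union > 0 else 0.0


def iou_matrix(boxes_a, boxes_b) -> np.ndarray:
    """Pairwise IoU, vectorized over two box collections."""
    if len(boxes_a) == 0 or len(boxes_b) == 0:
        return np.zeros((len(boxes_a), len(boxes_b)))
    a = np.asarray(boxes_a, dtype=float)
    b = np.asarray(boxes_b, dtype=float)
    ax1, ay1 = a[:, 0], a[:, 1]
    ax2, ay2 = a[:, 0] + a[:, 2], a[:, 1] + a[:, 3]
    bx1, by1 = b[:, 0], b[:, 1]
    bx2, by2 = b[:, 0] + b[:, 2], b[:, 1] + b[:, 3]
    ix = np.maximum(0.0, np.minimum(ax2[:, None], bx2) - np.maximum(ax1[:, None], bx1))
    iy = np.maximum(0.0, np.minimum(ay2[:, None], by2) - np.maximum(ay1[:, None], by1))
    inter = ix * iy
    union = (a[:, 2] * a[:, 3])[:, None] + b[:, 2] * b[:, 3] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def _direction(p_from, p_to) -> float | None:
    dx = p_to[0] - p_from[0]
    dy = p_to[1] - p_from[1]
    if dx == 0.0 and dy == 0.0:
        return None
    return math.atan2(dy, dx)


def velocity_consistency_cost(
    track_history: list[tuple[int, tuple[float, float]]],
    detection_center: tuple[float, float],
    delta_t: int = 3,
) -> float:
    """Direction-consistency cost in [0, 1].

    ``track_history`` is the track's real observations as (frame, center)
    pairs in frame order. The track direction is taken between the newest
    observation and the one ``delta_t`` frames earlier (oldest available
    if history is shorter); the link direction runs from that older
    reference observation to the detection center. Cost is the absolute
    angular difference normalized by pi. Zero when no direction is
    defined (single observation or coincident points).
    """
    if len(track_history) < 2:
        return 0.0
    newest_frame, newest = track_history[-1]
    ref = None
    for frame, center in track_history[:-1]:
        if frame <= newest_frame - delta_t:
            ref = (frame, center)
        else:
            break
    if ref is None:
        ref = track_history[0]  # history shorter than delta_t: oldest pair
    theta_track = _direction(ref[1], newest)
    theta_link = _direction(ref[1], detection_center)
    if theta_track is None or theta_link is None:
        return 0.0
    diff = abs(theta_track - theta_link) % (2 * math.pi)
    if diff > math.pi:
        diff = 2 * math.pi - diff
    return diff / math.pi


def build_cost(
    predicted_boxes,
    histories: list[list[tuple[int, tuple[float, float]]]],
    detections,
    lambda_weight: float = 0.2,
    delta_t: int = 3,
    iou_gate: float = 0.3,
) -> CostMatrix:
    """Assemble the association cost matrix.

    ``predicted_boxes``: per-track predicted (l, t, w, h) boxes.
    ``histories``: per-track observation histories for the momentum term.
    ``detections``: Detection objects (``.box`` attribute used).
    """
    det_boxes = [d.box for d in detections]
    ious = iou_matrix(predicted_boxes, det_boxes)
    n, m = ious.shape
    values = -ious
    if lambda_weight != 0.0 and n and m:
        cv = np.zeros((n, m))
        centers = [(b[0] + b[2] / 2.0, b[1] + b[3] / 2.0) for b in det_boxes]
        for i, hist in enumerate(histories):
            for j, c in enumerate(centers):
                cv[i, j] = velocity_consistency_cost(hist, c, delta_t)
        values = values + lambda_weight * cv
    return CostMatrix(values=values, feasible=ious >= iou_gate)


def solve_assignment(cost: CostMatrix) -> AssociationResult:
    """Minimum-cost one-to-one assignment over the feasible cells.

    Infeasible cells never enter a match; leftover rows/columns are
    reported unmatched. A tiny lexicographic perturbation breaks cost
    ties toward (lower track index, lower detection index).
    """
    values, feasible = cost.values, cost.feasible
    n, m = values.shape
    if n == 0 or m == 0 or not feasible.any():
        return AssociationResult((), tuple(range(n)), tuple(range(m)))
    big = 1e6
    # Leaving a track or detection unmatched costs 0, so the optimum can
    # skip pairs whose (gated) cost is positive: pad with zero-cost
    # dummies and solve the square (n+m) x (m+n) problem.
    real = np.where(feasible, values, big)
    # Deterministic tie-break: prefer low (i, j) among equal-cost optima.
    eps = 1e-10
    tie = eps * (np.arange(n)[:, None] * m + np.arange(m)[None, :])
    padded = np.zeros((n + m, m + n))
    padded[:n, :m] = real + tie
    rows, cols = linear_sum_assignment(padded)
    matches = tuple(
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and feasible[i, j] and values[i, j] <= 0
    )
    mt = {i for i, _ in matches}
    md = {j for _, j in matches}
    return AssociationResult(
        matches=matches,
        unmatched_tracks=tuple(i for i in range(n) if i not in mt),
        unmatched_detections=tuple(j for j in range(m) if j not in md),
    )


def ocr_associate(
    last_observed_boxes,
    detections,
    iou_gate: float = 0.3,
) -> AssociationResult:
    """Second-stage association for lost tracks.

    Matches each lost track's last *real* observed box against the
    detections left over from the primary stage, by negative IoU gated at
    ``iou_gate``. A stationary or slowly moving animal that reappears
    near where it was last seen is recovered here even when the filter's
    prediction has drifted away.
    """
    det_boxes = [d.box for d in detections]
    ious = iou_matrix(last_observed_boxes, det_boxes)
    return solve_assignment(CostMatrix(values=-ious, feasible=ious >= iou_gate))
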