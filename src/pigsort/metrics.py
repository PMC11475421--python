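"""Multi-object tracking evaluation: MOTA, IDF1, HOTA, identity switches.

Per-frame matching pairs ground-truth and predicted boxes by
minimum-cost bipartite matching on (1 - IoU), forbidding pairs below an
IoU threshold; leftovers are false negatives / false positives.

MOTA = 1 - (FP + FN + IDS) / total gt boxes, with an identity switch
counted whenever a gt identity's matched predicted id differs from the
id it matched most recently before.

IDF1 chooses one global bijection between gt and predicted identities
maximizing the number of per-frame box pairs above the IoU threshold
(IDTP), then scores 2*IDTP / (2*IDTP + IDFP + IDFN).

HOTA at a localization threshold alpha is sqrt(DetA * AssA): DetA is
TP / (TP + FN + FP); AssA averages, over true-positive pairs c = (g, p),
A(c) = TPA / (TPA + FNA + FPA) where TPA counts frames where g and p are
matched to each other and the denominator is |frames of g| +
|frames of p| - TPA. The headline HOTA averages over
alpha = 0.05, 0.10, ..., 0.95.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from pigsort.association import iou_matrix
from pigsort.io import TrackRow, read_tracks

logger = logging.getLogger(__name__)

__all__ = [
    "FrameMatching",
    "MetricsReport",
    "match_frames",
    "mota",
    "idf1",
    "hota",
    "evaluate",
    "evaluate_rows",
]

HOTA_ALPHAS = tuple(round(0.05 * k, 2) for k in range(1, 20))


@dataclass(frozen=True)
class FrameMatching:
    """Matching for one frame: TP id pairs plus FP/FN leftovers."""

    frame: int
    tp: tuple[tuple[int, int], ...]  # (gt_id, pred_id)
    fp: tuple[int, ...]  # unmatched pred ids
    fn: tuple[int, ...]  # unmatched gt ids


@dataclass
class MetricsReport:
    hota: float
    deta: float
    assa: float
    hota_single_alpha: float
    mota: float | None
    idf1: float
    ids: int
    fp: int
    fn: int
    tp: int
    idtp: int
    idfp: int
    idfn: int

    def to_dict(self) -> dict:
        return asdict(self)


def _group(rows: Sequence[TrackRow]) -> dict[int, list[TrackRow]]:
    out: dict[int, list[TrackRow]] = {}
    for r in rows:
        out.setdefault(r.frame, []).append(r)
    return out


def match_frames(
    gt_rows: Sequence[TrackRow],
    pred_rows: Sequence[TrackRow],
    alpha: float = 0.5,
) -> list[FrameMatching]:
    """Per-frame bipartite matching on (1 - IoU), gated at IoU >= alpha."""
    gt_by_frame = _group(gt_rows)
    pred_by_frame = _group(pred_rows)
    frames = sorted(set(gt_by_frame) | set(pred_by_frame))
    out: list[FrameMatching] = []
    for f in frames:
        gts = gt_by_frame.get(f, [])
        preds = pred_by_frame.get(f, [])
        ious = iou_matrix([r.box for r in gts], [r.box for r in preds])
        feasible = ious >= alpha
        tp: list[tuple[int, int]] = []
        if feasible.any():
            cost = np.where(feasible, 1.0 - ious, 1e6)
            ri, ci = linear_sum_assignment(cost)
            tp = [
                (gts[i].track_id, preds[j].track_id)
                for i, j in zip(ri, ci)
                if feasible[i, j]
            ]
        matched_gt = {g for g, _ in tp}
        matched_pred = {p for _, p in tp}
        out.append(
            FrameMatching(
                frame=f,
                tp=tuple(tp),
                fp=tuple(r.track_id for r in preds if r.track_id not in matched_pred),
                fn=tuple(r.track_id for r in gts if r.track_id not in matched_gt),
            )
        )
    return out


def count_switches(matchings: Sequence[FrameMatching]) -> int:
    """Identity switches: a gt identity's matched pred id changes between
    its consecutively matched frames."""
    last: dict[int, int] = {}
    ids = 0
    for fm in sorted(matchings, key=lambda m: m.frame):
        for g, p in fm.tp:
            if g in last and last[g] != p:
                ids += 1
            last[g] = p
    return ids


def mota(
    matchings: Sequence[FrameMatching], gt_rows: Sequence[TrackRow]
) -> float | None:
    """MOTA = 1 - (FP + FN + IDS) / total gt boxes; None when gt is empty."""
    total_gt = len(gt_rows)
    if total_gt == 0:
        return None
    fp = sum(len(m.fp) for m in matchings)
    fn = sum(len(m.fn) for m in matchings)
    ids = count_switches(matchings)
    return 1.0 - (fp + fn + ids) / total_gt


def idf1(
    gt_rows: Sequence[TrackRow],
    pred_rows: Sequence[TrackRow],
    alpha: float = 0.5,
) -> tuple[float, int, int, int]:
    """IDF1 with the optimal global identity bijection.

    Returns (idf1, idtp, idfp, idfn). For each (gt id, pred id) pair the
    potential IDTP is the number of frames where both are present and
    their boxes reach IoU >= alpha; a maximum-weight bipartite matching
    over identities picks the bijection.
    """
    gt_ids = sorted({r.track_id for r in gt_rows})
    pred_ids = sorted({r.track_id for r in pred_rows})
    n_gt, n_pred = len(gt_rows), len(pred_rows)
    if not gt_ids or not pred_ids:
        idtp = 0
    else:
        gi = {g: i for i, g in enumerate(gt_ids)}
        pi = {p: i for i, p in enumerate(pred_ids)}
        overlap = np.zeros((len(gt_ids), len(pred_ids)))
        gt_by_frame = _group(gt_rows)
        pred_by_frame = _group(pred_rows)
        for f in set(gt_by_frame) & set(pred_by_frame):
            gts = gt_by_frame[f]
            preds = pred_by_frame[f]
            ious = iou_matrix([r.box for r in gts], [r.box for r in preds])
            hit = ious >= alpha
            for a in range(len(gts)):
                for b in range(len(preds)):
                    if hit[a, b]:
                        overlap[gi[gts[a].track_id], pi[preds[b].track_id]] += 1
        ri, ci = linear_sum_assignment(-overlap)
        idtp = int(overlap[ri, ci].sum())
    idfp = n_pred - idtp
    idfn = n_gt - idtp
    denom = 2 * idtp + idfp + idfn
    return (2 * idtp / denom if denom else 1.0, idtp, idfp, idfn)


def hota(
    gt_rows: Sequence[TrackRow],
    pred_rows: Sequence[TrackRow],
    alpha: float,
) -> tuple[float, float, float]:
    """(HOTA_alpha, DetA, AssA) at a single localization threshold."""
    matchings = match_frames(gt_rows, pred_rows, alpha)
    tp_pairs: list[tuple[int, int]] = []
    for m in matchings:
        tp_pairs.extend(m.tp)
    tp = len(tp_pairs)
    fp = sum(len(m.fp) for m in matchings)
    fn = sum(len(m.fn) for m in matchings)
    if tp + fp + fn == 0:
        return 1.0, 1.0, 1.0
    deta = tp / (tp + fn + fp)
    if tp == 0:
        return 0.0, deta, 0.0
    pair_count: dict[tuple[int, int], int] = {}
    for c in tp_pairs:
        pair_count[c] = pair_count.get(c, 0) + 1
    gt_frames: dict[int, int] = {}
    for r in gt_rows:
        gt_frames[r.track_id] = gt_frames.get(r.track_id, 0) + 1
    pred_frames: dict[int, int] = {}
    for r in pred_rows:
        pred_frames[r.track_id] = pred_frames.get(r.track_id, 0) + 1
    assa_sum = 0.0
    for (g, p) in tp_pairs:
        tpa = pair_count[(g, p)]
        assa_sum += tpa / (gt_frames[g] + pred_frames[p] - tpa)
    assa = assa_sum / tp
    return float(np.sqrt(deta * assa)), deta, assa


def evaluate_rows(
    gt_rows: Sequence[TrackRow],
    pred_rows: Sequence[TrackRow],
    alpha: float = 0.5,
    hota_alphas: Sequence[float] = HOTA_ALPHAS,
) -> MetricsReport:
    """Full report from in-memory tables.

    ``alpha`` is the IoU threshold for the MOTA/IDF1 matching (the
    MOTChallenge convention is 0.5); HOTA additionally averages over
    ``hota_alphas``.
    """
    gt_frames = {r.frame for r in gt_rows}
    pred_frames = {r.frame for r in pred_rows}
    if pred_frames - gt_frames or (gt_frames and not pred_frames):
        warnings.warn(
            "frame ranges of ground truth and prediction differ; "
            "evaluating over the union of frames",
            stacklevel=2,
        )
    matchings = match_frames(gt_rows, pred_rows, alpha)
    fp = sum(len(m.fp) for m in matchings)
    fn = sum(len(m.fn) for m in matchings)
    tp = sum(len(m.tp) for m in matchings)
    ids = count_switches(matchings)
    mota_val = mota(matchings, gt_rows)
    idf1_val, idtp, idfp, idfn = idf1(gt_rows, pred_rows, alpha)
    per_alpha = [hota(gt_rows, pred_rows, a) for a in hota_alphas]
    hota_avg = float(np.mean([h for h, _, _ in per_alpha]))
    deta_avg = float(np.mean([d for _, d, _ in per_alpha]))
    assa_avg = float(np.mean([a for _, _, a in per_alpha]))
    hota_single, _, _ = hota(gt_rows, pred_rows, alpha)
    return MetricsReport(
        hota=hota_avg,
        deta=deta_avg,
        assa=assa_avg,
        hota_single_alpha=hota_single,
        mota=mota_val,
        idf1=idf1_val,
        ids=ids,
        fp=fp,
        fn=fn,
        tp=tp,
        idtp=idtp,
        idfp=idfp,
        idfn=idfn,
    )


def evaluate(gt_path, pred_path, alpha: float = 0.5) -> MetricsReport:
    """Evaluate a tracker-output file against a ground-truth file."""
    return evaluate_rows(read_tracks(gt_path), read_tracks(pred_path), alpha=alpha)
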