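"""Online observation-centric tracker: per-frame predict -> associate ->
recover -> update, with track lifecycle and behavior accounting.

Each frame: (1) every live track's filter is propagated one step;
(2) the primary association matches predicted boxes to detections with
the IoU + momentum cost; (3) leftover (lost) tracks get a second chance
against leftover detections via their last real observed box;
(4) matched tracks are updated — a track recovered after a gap of two or
more frames is first re-updated along a virtual trajectory interpolating
the gap, which discards the error accumulated while predicting blind;
(5) confident leftover detections found new tracks; (6) tracks unseen
for more than ``max_age`` frames are deleted. Output rows are emitted
only for tracks matched in the current frame, carrying the matched
detection's box and behavior class.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from pigsort.association import build_cost, ocr_associate, solve_assignment
from pigsort.behavior import BehaviorCounts
from pigsort.io import Detection, TrackRow
from pigsort.kalman import (
    BoxKalmanFilter,
    KalmanState,
    NoiseModel,
    box_to_z,
    make_virtual_trajectory,
    z_to_box,
)

logger = logging.getLogger(__name__)

ACTIVE = "active"
UNTRACKED = "untracked"
DELETED = "deleted"


@dataclass
class TrackerConfig:
    """Tunable tracker parameters.

    max_age: frames a track survives without a match before deletion.
    new_track_confidence: minimum detection confidence to found a track.
    lambda_weight: weight of the direction-consistency cost term.
    delta_t: frame span used to estimate a track's motion direction.
    iou_gate: minimum IoU for an association to be feasible (both stages).
    min_hits: consecutive matches before a track is emitted (1 = emit
        from birth; kept for completeness, no probation by default).
    enable_ocr / enable_oru: switch off the recovery association and the
        virtual-trajectory re-update (for ablation).
    """

    max_age: int = 30
    new_track_confidence: float = 0.7
    lambda_weight: float = 0.2
    delta_t: int = 3
    iou_gate: float = 0.3
    min_hits: int = 1
    enable_ocr: bool = True
    enable_oru: bool = True
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        if not 0.0 <= self.new_track_confidence <= 1.0:
            raise ValueError("new_track_confidence must be in [0,1]")


@dataclass(eq=False)
class Track:
    """One identity with its filter state, observation history and
    behavior frame counts (lie, stand, eat, other)."""

    id: int
    kf: KalmanState
    observations: dict[int, np.ndarray] = field(default_factory=dict)
    last_observed_frame: int = 0
    time_since_update: int = 0
    status: str = ACTIVE
    behavior_counts: BehaviorCounts = field(default_factory=BehaviorCounts)
    last_behavior: str | None = None
    hits: int = 0
    # posterior at the last real observation, the re-update starting point
    kf_at_last_obs: KalmanState | None = None

    def history(self) -> list[tuple[int, tuple[float, float]]]:
        """Real observations as (frame, center) pairs in frame order."""
        return [
            (f, (z[0], z[1])) for f, z in sorted(self.observations.items())
        ]

    def predicted_box(self) -> tuple[float, float, float, float]:
        return self.kf.box()

    def last_observed_box(self) -> tuple[float, float, float, float]:
        return z_to_box(self.observations[self.last_observed_frame])


class PigTracker:
    """Online multi-object tracker over a stream of per-frame detections."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config if config is not None else TrackerConfig()
        self.filter = BoxKalmanFilter(self.config.noise)
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    # -- public API --------------------------------------------------------

    def step(self, frame: int, detections: list[Detection]) -> list[TrackRow]:
        """Advance one frame; returns output rows for matched tracks."""
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(
                f"frames must be strictly increasing (got {frame} after {self._last_frame})"
            )
        self._last_frame = frame
        cfg = self.config

        live = [t for t in self.tracks if t.status != DELETED]
        for t in live:
            t.kf = self.filter.predict(t.kf)
            t.time_since_update += 1

        # primary association: predicted boxes + momentum cost
        cost = build_cost(
            [t.predicted_box() for t in live],
            [t.history() for t in live],
            detections,
            lambda_weight=cfg.lambda_weight,
            delta_t=cfg.delta_t,
            iou_gate=cfg.iou_gate,
        )
        result = solve_assignment(cost)
        matched: list[tuple[Track, Detection]] = [
            (live[i], detections[j]) for i, j in result.matches
        ]
        leftover_tracks = [live[i] for i in result.unmatched_tracks]
        leftover_dets = [detections[j] for j in result.unmatched_detections]

        # recovery association on last real observed boxes
        if cfg.enable_ocr and leftover_tracks and leftover_dets:
            recoverable = [t for t in leftover_tracks if t.observations]
            ocr = ocr_associate(
                [t.last_observed_box() for t in recoverable],
                leftover_dets,
                iou_gate=cfg.iou_gate,
            )
            rec_d = {j for _, j in ocr.matches}
            recovered_ids = set()
            for i, j in ocr.matches:
                matched.append((recoverable[i], leftover_dets[j]))
                recovered_ids.add(recoverable[i].id)
                logger.debug(
                    "frame %d: OCR recovered track %d", frame, recoverable[i].id
                )
            leftover_tracks = [
                t for t in leftover_tracks if t.id not in recovered_ids
            ]
            leftover_dets = [
                d for j, d in enumerate(leftover_dets) if j not in rec_d
            ]

        rows: list[TrackRow] = []
        for track, det in matched:
            self._update_track(track, det, frame)
            if track.hits >= cfg.min_hits:
                rows.append(
                    TrackRow(
                        frame=frame,
                        track_id=track.id,
                        box=det.box,
                        behavior=det.behavior,
                    )
                )

        for det in leftover_dets:
            if det.confidence >= cfg.new_track_confidence:
                rows_new = self._create_track(det, frame)
                if rows_new is not None:
                    rows.append(rows_new)

        for track in leftover_tracks:
            track.status = UNTRACKED
            if track.time_since_update > cfg.max_age:
                track.status = DELETED
                logger.debug("frame %d: deleted track %d", frame, track.id)

        rows.sort(key=lambda r: r.track_id)
        return rows

    # -- internals ---------------------------------------------------------

    def _update_track(self, track: Track, det: Detection, frame: int) -> None:
        cfg = self.config
        z = box_to_z(det.box)
        gap = frame - track.last_observed_frame
        if (
            cfg.enable_oru
            and track.kf_at_last_obs is not None
            and gap >= 2
        ):
            # replay the filter along the interpolated virtual trajectory
            z_t1 = track.observations[track.last_observed_frame]
            virtual = make_virtual_trajectory(
                z_t1, z, track.last_observed_frame, frame
            )
            track.kf = self.filter.re_update(track.kf_at_last_obs, virtual, z)
            logger.debug(
                "frame %d: ORU re-update of track %d over %d virtual frames",
                frame, track.id, len(virtual),
            )
        else:
            track.kf = self.filter.update(track.kf, z)
        track.observations[frame] = z
        track.last_observed_frame = frame
        track.time_since_update = 0
        track.status = ACTIVE
        track.hits += 1
        track.behavior_counts.increment(det.behavior)
        track.last_behavior = det.behavior
        track.kf_at_last_obs = copy.deepcopy(track.kf)

    def _create_track(self, det: Detection, frame: int) -> TrackRow | None:
        z = box_to_z(det.box)
        state = self.filter.initiate(z)
        track = Track(
            id=self._next_id,
            kf=state,
            observations={frame: z},
            last_observed_frame=frame,
            time_since_update=0,
            status=ACTIVE,
            last_behavior=det.behavior,
            hits=1,
            kf_at_last_obs=copy.deepcopy(state),
        )
        track.behavior_counts.increment(det.behavior)
        self._next_id += 1
        self.tracks.append(track)
        logger.debug("frame %d: created track %d", frame, track.id)
        if track.hits >= self.config.min_hits:
            return TrackRow(
                frame=frame, track_id=track.id, box=det.box, behavior=det.behavior
            )
        return None


def run_tracker(
    detections_by_frame: Mapping[int, list[Detection]],
    config: TrackerConfig | None = None,
    frame_range: Iterable[int] | None = None,
) -> tuple[list[TrackRow], list[Track]]:
    """Run the tracker over a whole stream.

    ``frame_range`` defaults to every frame from the first to the last
    key of ``detections_by_frame`` inclusive; frames without detections
    still advance prediction and aging.
    """
    tracker = PigTracker(config)
    rows: list[TrackRow] = []
    if frame_range is None:
        if not detections_by_frame:
            return [], []
        frames = sorted(detections_by_frame)
        frame_range = range(frames[0], frames[-1] + 1)
    for frame in frame_range:
        rows.extend(tracker.step(frame, detections_by_frame.get(frame, [])))
    return rows, tracker.tracks
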