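"""Per-animal behavior time accounting.

Each track carries a 4-vector of cumulative frame counts, one entry per
behavior category in the fixed order (lie, stand, eat, other). On every
successful association the matched detection's class increments exactly
one entry (a one-hot addition). Counts accrue only on matched frames;
frames where an animal is occluded or missed contribute to no category.
Dividing counts by the frame rate yields per-animal durations in
seconds; pooling counts over all tracks of a pen yields the herd-level
time budget as percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from pigsort.io import BEHAVIORS, TrackRow

__all__ = ["BehaviorCounts", "BehaviorReport", "behavior_report", "recount_from_rows"]

_INDEX = {b: i for i, b in enumerate(BEHAVIORS)}


@dataclass
class BehaviorCounts:
    """Cumulative frame counts [lie, stand, eat, other] for one track."""

    counts: list[int] = field(default_factory=lambda: [0, 0, 0, 0])

    def increment(self, behavior: str) -> "BehaviorCounts":
        if behavior not in _INDEX:
            raise ValueError(f"unknown behavior {behavior!r}")
        self.counts[_INDEX[behavior]] += 1
        return self

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass
class BehaviorReport:
    """Durations per track (seconds) and herd-level percentages.

    ``herd_percent`` is None when no frames were recorded at all;
    otherwise its four entries are frame-weighted percentages summing
    to 100.
    """

    per_track: dict[int, dict[str, float]]
    herd_percent: dict[str, float] | None
    total_frames_per_track: dict[int, int]
    fps: float

    def to_json(self) -> str:
        payload = {
            "fps": self.fps,
            "per_track": {
                str(tid): {f"{b}_s": secs[b] for b in BEHAVIORS}
                for tid, secs in self.per_track.items()
            },
            "total_frames_per_track": {
                str(tid): n for tid, n in self.total_frames_per_track.items()
            },
            "herd_percent": self.herd_percent,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_csv(self) -> str:
        lines = ["track_id," + ",".join(f"{b}_s" for b in BEHAVIORS)]
        for tid in sorted(self.per_track):
            secs = self.per_track[tid]
            lines.append(
                f"{tid}," + ",".join(repr(secs[b]) for b in BEHAVIORS)
            )
        return "\n".join(lines) + "\n"


def behavior_report(
    counts_by_track: dict[int, BehaviorCounts], fps: float
) -> BehaviorReport:
    """Convert accumulated frame counts to durations and percentages.

    Per-track durations are exactly counts / fps. Herd percentages pool
    frames over all tracks (frame-weighted), so long-observed animals
    weigh more than briefly seen ones.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    per_track: dict[int, dict[str, float]] = {}
    totals = [0, 0, 0, 0]
    total_frames: dict[int, int] = {}
    for tid, bc in counts_by_track.items():
        per_track[tid] = {b: bc.counts[i] / fps for i, b in enumerate(BEHAVIORS)}
        total_frames[tid] = bc.total
        for i in range(4):
            totals[i] += bc.counts[i]
    grand = sum(totals)
    herd = (
        {b: 100.0 * totals[i] / grand for i, b in enumerate(BEHAVIORS)}
        if grand > 0
        else None
    )
    return BehaviorReport(
        per_track=per_track,
        herd_percent=herd,
        total_frames_per_track=total_frames,
        fps=fps,
    )


def recount_from_rows(rows: list[TrackRow]) -> dict[int, BehaviorCounts]:
    """Independent recount of behavior frames from an emitted track table.

    Serves as a cross-check of the online accumulation: for every track,
    the recount must equal the counts accrued during tracking.
    """
    out: dict[int, BehaviorCounts] = {}
    for r in rows:
        out.setdefault(r.track_id, BehaviorCounts()).increment(r.behavior)
    return out
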