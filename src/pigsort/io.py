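"""Reading and writing MOTChallenge-style track files with a behavior column.

All three file kinds (raw detections, ground truth, tracker output) share
one comma-separated dialect::

    frame,id,left,top,width,height,confidence,class_index

Frames are 1-based; boxes are (left, top, width, height) in pixels with
the origin at the top-left; ``id`` is ``-1`` for raw detections and a
positive integer otherwise; ``class_index`` maps 1=lie, 2=stand, 3=eat,
4=other. Numbers use a decimal point only (locale-independent).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

BEHAVIORS: tuple[str, ...] = ("lie", "stand", "eat", "other")
_CLASS_TO_BEHAVIOR = {i + 1: b for i, b in enumerate(BEHAVIORS)}
_BEHAVIOR_TO_CLASS = {b: i + 1 for i, b in enumerate(BEHAVIORS)}


class ParseError(ValueError):
    """Raised for malformed rows; message names the offending line."""


@dataclass(frozen=True)
class Detection:
    """One detector output box on one frame.

    ``box`` is (left, top, width, height) in pixels; ``confidence`` lies
    in [0, 1]; ``behavior`` is one of :data:`BEHAVIORS`.
    """

    frame: int
    box: tuple[float, float, float, float]
    confidence: float
    behavior: str

    def __post_init__(self) -> None:
        if self.box[2] <= 0 or self.box[3] <= 0:
            raise ValueError(f"box must have positive size, got {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")


@dataclass(frozen=True)
class TrackRow:
    """One (frame, identity) row of a ground-truth or tracker-output table."""

    frame: int
    track_id: int
    box: tuple[float, float, float, float]
    behavior: str

    def __post_init__(self) -> None:
        if self.track_id <= 0:
            raise ValueError(f"track_id must be positive, got {self.track_id}")
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")


@dataclass(frozen=True)
class SequenceMeta:
    """Sequence-level metadata (one file = one pen)."""

    fps: float = 5.0
    image_width: int = 2688
    image_height: int = 1520
    name: str = "sequence"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")


def _parse_row(line: str, lineno: int, path: str) -> tuple:
    parts = line.split(",")
    if len(parts) != 8:
        raise ParseError(
            f"{path}:{lineno}: expected 8 comma-separated fields, got {len(parts)}"
        )
    try:
        frame = int(parts[0])
        obj_id = int(parts[1])
        left, top, width, height = (float(p) for p in parts[2:6])
        conf = float(parts[6])
        class_index = int(parts[7])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None
    if class_index not in _CLASS_TO_BEHAVIOR:
        raise ParseError(
            f"{path}:{lineno}: unknown class_index {class_index} (expected 1-4)"
        )
    return frame, obj_id, (left, top, width, height), conf, _CLASS_TO_BEHAVIOR[class_index]


def read_detections(path: str | os.PathLike) -> dict[int, list[Detection]]:
    """Read raw detections, grouped by frame.

    Returns a dict mapping frame index to detections sorted by descending
    confidence. Frames absent from the file are absent from the dict;
    callers iterating a frame range treat missing keys as empty frames.
    """
    groups: dict[int, list[Detection]] = {}
    with open(path, encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            frame, _, box, conf, behavior = _parse_row(line, lineno, str(path))
            groups.setdefault(frame, []).append(
                Detection(frame=frame, box=box, confidence=conf, behavior=behavior)
            )
    for dets in groups.values():
        dets.sort(key=lambda d: -d.confidence)
    return dict(sorted(groups.items()))


def read_tracks(path: str | os.PathLike) -> list[TrackRow]:
    """Read a ground-truth or tracker-output table, sorted by (frame, id).

    Raises :class:`ParseError` if a (frame, id) pair occurs twice.
    """
    rows: list[TrackRow] = []
    seen: set[tuple[int, int]] = set()
    with open(path, encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            frame, obj_id, box, _, behavior = _parse_row(line, lineno, str(path))
            if obj_id <= 0:
                raise ParseError(
                    f"{path}:{lineno}: track rows need a positive id, got {obj_id}"
                )
            if (frame, obj_id) in seen:
                raise ParseError(f"{path}:{lineno}: duplicate (frame,id) ({frame},{obj_id})")
            seen.add((frame, obj_id))
            rows.append(TrackRow(frame=frame, track_id=obj_id, box=box, behavior=behavior))
    rows.sort(key=lambda r: (r.frame, r.track_id))
    return rows


def _fmt(x: float) -> str:
    # Integral values print without a trailing ".0" so round-trips are stable.
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_tracks(rows: Iterable[TrackRow], path: str | os.PathLike) -> None:
    """Write track rows in the shared dialect (confidence fixed at 1)."""
    with open(path, "w", encoding="ascii") as fh:
        for r in rows:
            l, t, w, h = r.box
            fh.write(
                f"{r.frame},{r.track_id},{_fmt(l)},{_fmt(t)},{_fmt(w)},{_fmt(h)},1,"
                f"{_BEHAVIOR_TO_CLASS[r.behavior]}\n"
            )


def write_detections(dets: Iterable[Detection], path: str | os.PathLike) -> None:
    """Write raw detections (id column fixed at -1)."""
    with open(path, "w", encoding="ascii") as fh:
        for d in dets:
            l, t, w, h = d.box
            fh.write(
                f"{d.frame},-1,{_fmt(l)},{_fmt(t)},{_fmt(w)},{_fmt(h)},"
                f"{_fmt(d.confidence)},{_BEHAVIOR_TO_CLASS[d.behavior]}\n"
            )
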