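"""Synthetic pen scenes and degraded detection streams.

Stands in for overhead pen recordings: each animal is a bounding box
doing a behavior-dependent bounded random walk with direction
persistence (reflecting at the pen walls, so motion is nonlinear at the
boundary). A per-frame Markov chain drives the behavior state — lying
and eating are near-stationary, standing and "other" are mobile, which
mirrors the observation that activity level governs tracking
difficulty. The detector is emulated at the box level: Gaussian jitter
on box centers and sizes, per-frame misses, longer occlusion dropouts
with geometric length, uniform-random false positives, and a confidence
model for true and false boxes.

Default regime: 8 animals in a 1280x720 pen at 5 fps for 60 s, with
day-like noise (2 px jitter, 2% miss rate, occasional multi-frame
occlusions). Typical pens hold 6-16 animals.

A deterministic ``degrade`` surgery mode removes exactly the frames and
injects exactly the false positives a test asks for, so metric fixtures
have exactly known error counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pigsort.io import BEHAVIORS, Detection, TrackRow

__all__ = [
    "SceneConfig",
    "generate_scene",
    "degrade",
    "default_transition",
    "single_gap_scenario",
]


def default_transition() -> np.ndarray:
    """Sticky behavior transitions (per frame at 5 fps): bouts last tens
    of seconds; lying dominates the stationary distribution, as in
    healthy herds."""
    return np.array(
        [
            # to:  lie     stand   eat     other
            [0.995, 0.003, 0.001, 0.001],  # from lie
            [0.006, 0.988, 0.004, 0.002],  # from stand
            [0.002, 0.006, 0.990, 0.002],  # from eat
            [0.002, 0.006, 0.002, 0.990],  # from other
        ]
    )


@dataclass
class SceneConfig:
    """Parameters of one simulated pen recording."""

    n_pigs: int = 8
    fps: float = 5.0
    duration_s: float = 60.0
    pen: tuple[int, int] = (1280, 720)
    behavior_transition: np.ndarray = field(default_factory=default_transition)
    speed_by_behavior: dict[str, float] = field(
        default_factory=lambda: {"lie": 0.0, "stand": 3.0, "eat": 0.2, "other": 5.0}
    )
    box_size: tuple[float, float] = (90.0, 60.0)  # typical grower pig, px
    direction_persistence: float = 0.9  # AR(1) coefficient on heading
    occlusion_rate: float = 0.0  # per-pig per-frame dropout start prob
    occlusion_len: float = 5.0  # geometric mean dropout length, frames
    det_noise_px: float = 0.0  # Gaussian std on centers and sizes
    fp_rate: float = 0.0  # expected false positives per frame
    miss_rate: float = 0.0  # per-visible-pig miss probability
    conf_true: tuple[float, float] = (0.9, 0.05)  # mean/std, true boxes
    conf_false: tuple[float, float] = (0.4, 0.1)  # mean/std, false boxes
    seed: int = 0

    def __post_init__(self) -> None:
        self.behavior_transition = np.asarray(self.behavior_transition, dtype=float)
        if not np.allclose(self.behavior_transition.sum(axis=1), 1.0):
            raise ValueError("behavior_transition rows must sum to 1")
        for name in ("occlusion_rate", "miss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        w, h = self.box_size
        if self.n_pigs * w * h > 0.8 * self.pen[0] * self.pen[1]:
            raise ValueError("n_pigs boxes cannot plausibly fit the pen")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


def _clip_box(cx, cy, w, h, pen):
    l = min(max(cx - w / 2, 0.0), pen[0] - w)
    t = min(max(cy - h / 2, 0.0), pen[1] - h)
    return (l, t, w, h)


def generate_scene(
    config: SceneConfig,
) -> tuple[list[TrackRow], dict[int, list[Detection]], list[TrackRow]]:
    """Simulate one pen.

    Returns (gt_rows, detections_by_frame, behavior_truth). The behavior
    truth equals the gt rows (the gt table carries the class column);
    it is returned separately for symmetry with file outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pigs
    pen_w, pen_h = config.pen
    bw, bh = config.box_size
    n_frames = config.n_frames

    # initial placement on a jittered grid so boxes do not overlap at birth
    cols = int(np.ceil(np.sqrt(n)))
    rows_n = int(np.ceil(n / cols))
    xs = np.linspace(bw, pen_w - bw, cols)
    ys = np.linspace(bh, pen_h - bh, rows_n)
    centers = []
    for i in range(n):
        cx = xs[i % cols] + rng.normal(0, 5)
        cy = ys[i // cols] + rng.normal(0, 5)
        centers.append([cx, cy])
    centers = np.array(centers)
    headings = rng.uniform(-np.pi, np.pi, size=n)
    behaviors = rng.integers(0, 4, size=n)

    gt_rows: list[TrackRow] = []
    visible_gt: dict[int, list[tuple[int, tuple, str]]] = {}
    occluded_until = np.zeros(n, dtype=int)

    # pre-draw the full behavior/motion history
    for f in range(1, n_frames + 1):
        for i in range(n):
            behaviors[i] = rng.choice(4, p=config.behavior_transition[behaviors[i]])
            speed = config.speed_by_behavior[BEHAVIORS[behaviors[i]]]
            # persistent heading: small unbiased turns each frame
            headings[i] += rng.normal(0, (1.0 - config.direction_persistence) * np.pi)
            centers[i, 0] += speed * np.cos(headings[i])
            centers[i, 1] += speed * np.sin(headings[i])
            # reflect at pen walls (nonlinear motion events by design)
            for d, lim in ((0, pen_w), (1, pen_h)):
                half = (bw if d == 0 else bh) / 2
                if centers[i, d] < half:
                    centers[i, d] = 2 * half - centers[i, d]
                    headings[i] = np.pi - headings[i] if d == 0 else -headings[i]
                elif centers[i, d] > lim - half:
                    centers[i, d] = 2 * (lim - half) - centers[i, d]
                    headings[i] = np.pi - headings[i] if d == 0 else -headings[i]
            box = _clip_box(centers[i, 0], centers[i, 1], bw, bh, config.pen)
            behavior = BEHAVIORS[behaviors[i]]
            gt_rows.append(
                TrackRow(frame=f, track_id=i + 1, box=box, behavior=behavior)
            )
            visible_gt.setdefault(f, []).append((i + 1, box, behavior))

    # detector emulation
    detections: dict[int, list[Detection]] = {f: [] for f in range(1, n_frames + 1)}
    for f in range(1, n_frames + 1):
        for pig_id, box, behavior in visible_gt[f]:
            i = pig_id - 1
            if f < occluded_until[i]:
                continue
            if config.occlusion_rate > 0 and rng.random() < config.occlusion_rate:
                length = rng.geometric(1.0 / max(config.occlusion_len, 1.0))
                occluded_until[i] = f + length
                continue
            if config.miss_rate > 0 and rng.random() < config.miss_rate:
                continue
            l, t, w, h = box
            if config.det_noise_px > 0:
                l += rng.normal(0, config.det_noise_px)
                t += rng.normal(0, config.det_noise_px)
                w = max(4.0, w + rng.normal(0, config.det_noise_px))
                h = max(4.0, h + rng.normal(0, config.det_noise_px))
            conf = (
                1.0
                if config.det_noise_px == 0
                else float(np.clip(rng.normal(*config.conf_true), 0.0, 1.0))
            )
            detections[f].append(
                Detection(frame=f, box=(l, t, w, h), confidence=conf, behavior=behavior)
            )
        if config.fp_rate > 0:
            for _ in range(rng.poisson(config.fp_rate)):
                w = rng.uniform(0.5 * bw, 1.5 * bw)
                h = rng.uniform(0.5 * bh, 1.5 * bh)
                l = rng.uniform(0, pen_w - w)
                t = rng.uniform(0, pen_h - h)
                conf = float(np.clip(rng.normal(*config.conf_false), 0.0, 1.0))
                detections[f].append(
                    Detection(
                        frame=f,
                        box=(l, t, w, h),
                        confidence=conf,
                        behavior=BEHAVIORS[int(rng.integers(0, 4))],
                    )
                )
        detections[f].sort(key=lambda d: -d.confidence)
    return gt_rows, detections, list(gt_rows)


def single_gap_scenario(
    gap: int,
    seed: int,
    pre_frames: int = 5,
    post_frames: int = 10,
    det_noise_px: float = 2.0,
    speed: float = 0.8,
    box_size: tuple[float, float] = (80.0, 60.0),
) -> tuple[dict[int, list[Detection]], int, int]:
    """One slow constant-velocity animal with a single detection dropout.

    The animal is observed for ``pre_frames`` frames, vanishes for
    ``gap`` frames, then reappears for ``post_frames`` frames; boxes
    carry Gaussian jitter. The short pre-gap history means the filter's
    velocity estimate is poorly converged when the animal is lost — the
    regime where recovery via the last observed box matters most. The
    default speed is a slow walk (0.8 px/frame at 5 fps).

    Returns (detections_by_frame, last_pre_gap_frame,
    first_post_gap_frame).
    """
    rng = np.random.default_rng(seed)
    heading = rng.uniform(-np.pi, np.pi)
    vx, vy = speed * np.cos(heading), speed * np.sin(heading)
    cx, cy = 600.0, 400.0
    bw, bh = box_size
    n_frames = pre_frames + gap + post_frames
    observed = set(range(1, pre_frames + 1)) | set(
        range(pre_frames + gap + 1, n_frames + 1)
    )
    dets: dict[int, list[Detection]] = {}
    for f in range(1, n_frames + 1):
        dets[f] = []
        if f not in observed:
            continue
        x = cx + vx * (f - 1)
        y = cy + vy * (f - 1)
        l = x - bw / 2 + rng.normal(0, det_noise_px)
        t = y - bh / 2 + rng.normal(0, det_noise_px)
        w = max(4.0, bw + rng.normal(0, det_noise_px))
        h = max(4.0, bh + rng.normal(0, det_noise_px))
        dets[f].append(
            Detection(frame=f, box=(l, t, w, h), confidence=0.95, behavior="stand")
        )
    return dets, pre_frames, pre_frames + gap + 1


def degrade(
    gt_rows: list[TrackRow],
    miss_frames: dict[int, list[int]] | None = None,
    inject_fp: list[Detection] | None = None,
    det_noise_px: float = 0.0,
    miss_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[int, list[Detection]], dict[str, int]]:
    """Corrupt an existing ground-truth table into a detection stream.

    ``miss_frames`` maps track_id -> frames to drop deterministically
    (exact-count surgery for metric fixtures); ``inject_fp`` appends the
    given false-positive detections verbatim. Random corruption
    (``det_noise_px``, ``miss_rate``) is applied on top, seeded.

    Returns (detections_by_frame, injected) where ``injected`` records
    the exact number of dropped gt boxes and added false positives.
    """
    rng = np.random.default_rng(seed)
    miss_frames = miss_frames or {}
    inject_fp = inject_fp or []
    detections: dict[int, list[Detection]] = {}
    dropped = 0
    for r in gt_rows:
        detections.setdefault(r.frame, [])
        if r.frame in miss_frames.get(r.track_id, []):
            dropped += 1
            continue
        if miss_rate > 0 and rng.random() < miss_rate:
            dropped += 1
            continue
        l, t, w, h = r.box
        if det_noise_px > 0:
            l += rng.normal(0, det_noise_px)
            t += rng.normal(0, det_noise_px)
            w = max(4.0, w + rng.normal(0, det_noise_px))
            h = max(4.0, h + rng.normal(0, det_noise_px))
        detections[r.frame].append(
            Detection(frame=r.frame, box=(l, t, w, h), confidence=1.0, behavior=r.behavior)
        )
    for d in inject_fp:
        detections.setdefault(d.frame, []).append(d)
    for dets in detections.values():
        dets.sort(key=lambda d: -d.confidence)
    return detections, {"dropped": dropped, "injected_fp": len(inject_fp)}
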