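import numpy as np
import pytest

from pigsort.io import BEHAVIORS, Detection, TrackRow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rows(rng, n=100, n_ids=5, n_frames=40):
    """Random well-formed track rows with unique (frame, id) pairs."""
    rows = []
    pairs = set()
    while len(rows) < n:
        frame = int(rng.integers(1, n_frames + 1))
        tid = int(rng.integers(1, n_ids + 1))
        if (frame, tid) in pairs:
            continue
        pairs.add((frame, tid))
        box = (
            float(rng.uniform(0, 1000)),
            float(rng.uniform(0, 600)),
            float(rng.uniform(10, 120)),
            float(rng.uniform(10, 120)),
        )
        rows.append(
            TrackRow(
                frame=frame,
                track_id=tid,
                box=box,
                behavior=BEHAVIORS[int(rng.integers(0, 4))],
            )
        )
    rows.sort(key=lambda r: (r.frame, r.track_id))
    return rows


def det(frame, box, conf=0.9, behavior="stand"):
    return Detection(frame=frame, box=box, confidence=conf, behavior=behavior)
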