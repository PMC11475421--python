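# pigsort

Observation-centric multi-object tracking and behavior-time analysis for
group-housed pigs.

Automated welfare monitoring in commercial pens needs each animal followed
individually over long periods: how long every pig lies, stands, eats. A
detector proposes per-frame bounding boxes with a behavior class; the hard
part is linking those boxes into stable identities despite occlusion,
clustering and lighting changes, and turning the linked stream into
per-animal time budgets. `pigsort` implements that linking-and-accounting
stage as a library and CLI, together with the standard tracking metrics
(HOTA, MOTA, IDF1, identity switches) and a synthetic pen-scene generator
so the whole pipeline runs and is testable without video or a trained
detector.

## Method

Tracking-by-detection with a constant-velocity Kalman filter on the 7-D
box state x = (u, v, s, r, u̇, v̇, ṡ) — center, area, aspect ratio and
their per-frame rates (r is held constant). Each frame:

1. **Predict** every live track: x̂ₜ = F xₜ₋₁, Pₜ = F Pₜ₋₁ Fᵀ + Q.
2. **Associate** predicted boxes with detections by the Hungarian
   algorithm on C = −IoU + λ·C_v, where C_v is the angular difference
   (normalized by π) between a track's historical motion direction and
   the direction implied by the candidate link — the
   *observation-centric momentum* term that suppresses direction-
   inconsistent matches in crowded pens.
3. **Recover** lost tracks: leftovers are matched a second time against
   leftover detections using the track's *last real observed box*
   instead of the drifted prediction (*observation-centric recovery*).
4. **Re-update**: a track recovered after a gap of ≥ 2 frames first
   replays its filter along a linearly interpolated *virtual trajectory*
   spanning the gap (*observation-centric re-update*), discarding the
   error accumulated while predicting blind; then the usual Kalman
   update K = P Hᵀ(H P Hᵀ + R)⁻¹, x ← x + K(z − H x), P ← (I − KH) P.
5. **Lifecycle**: unmatched detections with confidence ≥ 0.7 found new
   tracks; tracks unmatched for more than 30 frames are deleted.

Each matched detection's behavior class (lie / stand / eat / other)
increments one entry of the track's count vector [A1..A4]; dividing by
the frame rate gives per-animal durations, and pooling counts over all
tracks of a pen gives the herd time budget.

## Worked example

Simulate a day-like noisy pen (8 pigs, 60 s at 5 fps, 2 px detection
jitter, 2% misses, occasional multi-frame occlusions), track it, score
it, and account behavior time:

```bash
pigsort simulate --out-dir demo --seed 7 --n-pigs 8 --duration-s 60 \
    --det-noise-px 2 --miss-rate 0.02 --occlusion-rate 0.005
pigsort track --det demo/det.txt --out demo/out.txt
pigsort evaluate --gt demo/gt.txt --pred demo/out.txt --report demo/report.json
pigsort analyze-behavior --tracks demo/out.txt --fps 5 --report demo/behavior.json
```

The evaluate step prints:

```
HOTA 0.8784  MOTA 0.9725  IDF1 0.9861  IDS 0  FP 0  FN 66
```

i.e. on this degraded scene the tracker keeps every identity (no
switches), loses 66 of 2400 ground-truth boxes to simulated misses and
occlusions (MOTA 0.97), and associates what it detects almost perfectly
(IDF1 0.99; HOTA 0.88 additionally averages localization quality over
IoU thresholds). `demo/behavior.json` then holds the time budget, e.g.
pig 1 spent 14.6 s lying, 39.8 s standing, 3.6 s in "other" and 0 s
eating, and the herd split is lie 34.3% / stand 22.4% / eat 20.5% /
other 22.8% of tracked frames.

File formats are MOTChallenge-style CSV
(`frame,id,left,top,width,height,conf,class`) with the behavior class in
column 8; see `pigsort.io`.

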