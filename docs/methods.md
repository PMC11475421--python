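# Methods

## Motion model

Each animal's bounding box is filtered with a linear-Gaussian
constant-velocity model on the 7-D state (u, v, s, r, u̇, v̇, ṡ): center
in px, area in px², aspect ratio (dimensionless, no process velocity —
pigs seen from above change aspect slowly and erratically, so modeling
an aspect rate adds noise without signal), and per-frame rates. The
transition F adds each rate to its level once per frame; the time step
is fixed at one frame because detections arrive at a constant rate
(5 fps by default) and the file dialect carries no timestamps.

Noise defaults (all config-exposed, SORT-family convention):

- R = diag(1, 1, 10, 10): ~1 px center jitter; area/aspect measurements
  are noisier.
- Q = diag(1, 1, 1, 1, 1e-2, 1e-2, 1e-4): slowly varying velocities,
  with the area rate most constrained — it otherwise destabilizes long
  blind predictions.
- Initial covariance diag(10,…,10, 1e4, 1e4, 1e4): velocities are
  unobserved at birth, so they start with 1000× the position variance.

None of the package's guarantees depend on these exact values; they set
convergence speed, not contracts. A guard zeroes the area rate whenever
a prediction would drive the area non-positive (long occlusions can
otherwise produce invalid boxes).

## Association

Cost for track i, detection j:  C[i,j] = −IoU(x̂ᵢ, zⱼ) + λ·C_v(i,j),
gated infeasible where IoU < `iou_gate`. C_v is |θ_track − θ_link| / π,
with θ_track the direction between the track's newest real observation
and the one `delta_t` frames earlier (oldest available if the history is
shorter) and θ_link the direction from that reference observation to the
detection center. Normalizing by π keeps C_v in [0, 1], so λ directly
trades off overlap against direction consistency. Virtual observations
never enter the history: momentum is computed from real evidence only.

Defaults λ = 0.2, `delta_t` = 3, `iou_gate` = 0.3 follow the published
conventions of the observation-centric tracker family. One gate serves
both association stages.

The assignment is solved exactly (scipy's Hungarian implementation) on a
matrix padded with zero-cost dummy rows/columns, so leaving a pair
unmatched is always an option and positive-cost pairs are never forced
into a match; a tiny index-ordered perturbation (1e-10) makes
tie-breaking deterministic toward lower track/detection indices. Tests
pin optimality against exhaustive enumeration up to 6×6.

## Recovery and re-update

Tracks unmatched in the primary stage keep predicting ("untracked"
status) and still compete in the next frame's primary association. In
the same frame they get a second association: last real observed box vs
leftover detections, IoU only. When a track is re-associated after a gap
of g ≥ 2 frames, the filter is rewound to its posterior at the last real
observation and replayed through predict/update over a virtual
trajectory that linearly interpolates (u, v, s, r) across the gap,
finishing with the real re-associated observation. The linear form of
the virtual trajectory is this package's choice; it is exact for
constant-velocity gaps and a first-order approximation otherwise.

Tracks die after `max_age` = 30 consecutive unmatched frames; ids are
never reused. New tracks require detection confidence ≥ 0.7 and emit
output from their first frame (`min_hits` = 1; no probation stage). A
confidence threshold of 0.75 appears in some accounts of this design —
the package standardizes on 0.7 and leaves it configurable, which makes
the discrepancy moot.

## Behavior accounting

Category order is fixed as (lie, stand, eat, other) = (A1, A2, A3, A4).
Each successful association adds a one-hot increment from the matched
detection's class — the output label is the detection's class, not a
smoothed label. Occluded (unmatched) frames contribute to no category,
so per-track counts always equal the number of emitted rows for that
track (a recount-based test enforces this conservation). Durations are
counts / fps exactly; herd percentages pool frames over all tracks of a
sequence (frame-weighted, so long-observed animals weigh more — the
alternative of averaging per-animal percentages was rejected because it
over-weights briefly tracked, likely spurious ids). With zero recorded
frames the percentages are reported as null, never NaN.

## Evaluation metrics

Per-frame matching: Hungarian on (1 − IoU), pairs below IoU α forbidden;
default α = 0.5 (MOTChallenge convention). MOTA = 1 − (FP+FN+IDS)/gt,
with an identity switch counted when a ground-truth identity's matched
predicted id differs from its most recent previously matched id
(CLEAR-MOT convention). IDF1 uses the optimal global identity bijection
maximizing IDTP. HOTA_α = √(DetA·AssA) with
A(c) = TPA/(|frames of g| + |frames of p| − TPA); the headline HOTA
averages α over 0.05…0.95 (the ecosystem-standard definition), and the
single-α value is exposed alongside for comparison. The geometric-mean
identity HOTA² = DetA·AssA holds exactly per α; the α-averaged report
fields are means of the per-α values, so the identity is only approximate
across the averaged fields.

Empty ground truth makes MOTA undefined (null). Mismatched frame ranges
evaluate over the union of frames with a warning.

## Synthetic scenes

The generator emulates overhead pen recordings at the box level: n
animals (6–16 typical; default 8) in a 1280×720 px pen at 5 fps, boxes
90×60 px (grower-pig scale). Behavior states evolve by a sticky per-frame
Markov chain whose stationary law is lie-dominated (≈ 43/26/17/13% for
lie/stand/eat/other) with bouts lasting tens of seconds; behavior drives
kinematics (lie 0 px/frame, eat 0.2, stand 3, other 5) with persistent
headings and reflection at pen walls, so boundary motion is nonlinear by
design. The detector emulation applies Gaussian box jitter, per-frame
misses, geometric-length occlusion dropouts, uniform false positives and
a Gaussian confidence model. Occlusion is modeled as detection dropout,
not box merging — sufficient to exercise the recovery machinery, which
operates on missing observations.

What the simulator does *not* capture: appearance, pig-pig contact and
box merging during clustering, detector-correlated errors (misses
concentrated where pigs cluster), lighting-dependent noise, and class
confusion between behaviors. Passing tests therefore demonstrate the
correctness of the linking, accounting and scoring machinery under
controlled statistics, not detector-level performance on real video.

A deterministic surgery mode (`degrade`) drops exactly the frames and
injects exactly the false positives a fixture asks for, so metric tests
know their error counts by construction. The single-gap recovery
scenario uses a slow (0.8 px/frame) constant-velocity target observed
for only 5 frames before a 2–30 frame dropout with 2 px detection
jitter: short pre-gap history leaves the velocity estimate poorly
converged, which is precisely the regime where recovering via the last
observed box outperforms blind prediction.

## Problem sizes

Default verification runs use 8-pig, 60 s scenes (2400 ground-truth
boxes), 100 single-gap scenarios, and 50 seeded behavior-accounting
runs; the full suite and the acceptance script each complete in well
under a minute on one CPU.

## Known limitations

- Identity is motion-only; two pigs swapping positions during a mutual
  occlusion can swap ids (no appearance model).
- The linear virtual trajectory misrepresents sharply turning animals;
  re-update then converges to the real observation but intermediate
  states are approximate.
- Behavior time is undercounted during occlusion by design; reported
  durations are lower bounds on true time budgets.
- The evaluation ignores behavior-class agreement; metrics score
  identity and localization only.
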