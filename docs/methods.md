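# Methods

## The experiment being modeled

A small number (typically 4–6) of second-instar *Drosophila* larvae crawl
on a 22 × 22 cm agar gel filmed from above at 10 Hz. Larvae abandon
exploration when they reach a wall, so a robotic manipulator picks up any
animal that nears the arena edge and drops it back at the center; the arm
briefly occludes the camera, dropping frames. Optionally a linear thermal
gradient (13 °C to 21 °C across the arena, 0.035 °C/mm, centered at 17 °C)
drives cold-avoidance thermotaxis. At the image scale used, each ~1 mm
larva appears as a cluster of roughly 30 uniformly bright pixels on a dark
background.

Because raw video from such experiments is not generally available, the
package pairs every analysis stage with a generative simulator that emits
full ground truth, so the whole chain is testable end to end.

## Locomotion model

Crawling is a modified 2D random walk alternating **runs** and **turns**.

- *Runs*: the animal advances at speed `v(t)` along its heading, which
  diffuses with standard deviation `heading_diffusion` per √s (default
  5 deg/√s — runs are fairly straight; larger values start to blur the
  run/turn distinction at 10 Hz).
- *Turn initiation* is a Poisson process with base rate λ
  (`base_turn_rate_per_min`, default 2/min): per frame the probability is
  1 − exp(−λ_eff·dt).
- *Turns* rotate the heading at constant rate toward a drawn magnitude over
  `turn_duration_s` (default 2 s) with near-zero translation (10% of run
  speed — below the analysis speed floor, so turn frames drop out of
  speed-based summaries). Turn magnitude is a truncated Gaussian (mean 60°,
  sd 30°, bounds [20°, 180°]); the turn is to the left with probability
  `handedness_bias` (default 0.5). During a turn the body bend rises and
  falls as a half-sine with peak `max(45°, min(size, 120°))` — larvae sweep
  their heads widely even for small net heading changes, and this
  pronounced bend is what the state classifier keys on.
- *Activity decline*: speed falls linearly at `speed_decline_mm_s2`
  (default −6.9 × 10⁻⁵ mm/s², the first-hour decline observed in long
  continuous recordings) for `decline_duration_s` (1 h) and then plateaus,
  floored at `min_speed_mm_s` (0.1 mm/s). Base speed defaults to 0.5 mm/s,
  giving a plateau near 0.25 mm/s.

**Thermotaxis** is implemented as pure klinokinesis: the turn rate is
modulated by the heading ψ relative to the warm axis,

    λ_eff = λ · (1 + g · max(0, −cos ψ)),

so turns come sooner while crawling toward the cold side and runs toward
warmth last longer. No weathervaning and no turn-direction bias is modeled —
this is the simplest mechanism consistent with turn-rate-based gradient
navigation. The gain calibrated to reproduce a robot-mediated population
navigation index of ≈ 0.13 (the magnitude of robust larval cold avoidance)
is `CALIBRATED_THERMOTAXIS_GAIN = 1.25`; the `SimParams` default is 0
(taxis off). Note that measuring a clean NI at this effect size relies on
the transport robot: with wall bouncing instead of recentering, boundary
interactions suppress the measured index.

**Body model.** The body is two chords of length L/2 (L = 1 mm) meeting at
a joint, with the head chord at `heading + dir·bend/2` and the tail chord
at `heading − dir·bend/2`; the joint is placed so the body centroid
coincides with the animal's position. The renderer draws a stadium of width
0.22 mm around this midline, which at the default pixel scale
(0.09 mm/px) yields ~31-pixel clusters whose mask centroid matches the
ground-truth position to well under half a pixel.

**Robot controller.** When an animal enters the edge margin (default
15 mm) the controller attempts a pick-up: Bernoulli per attempt with
first-try probability 0.90; after 3 consecutive failures the calibration is
perturbed, nudging the per-attempt probability up by 0.05 (reinforcement of
the calibration parameters). A successful pick-up is followed by a drop-off
attempt sequence (first-try 0.95) at the arena center (±2 mm jitter). Each
manipulation occludes the camera for 10 s of dropped frames (the value is
config-exposed; only "brief" occlusion is known). A pick-up that exhausts
`max_attempts` leaves the animal in place, logs a failed event and backs
off for 30 s; a drop-off that exhausts its attempts still places the larva
(it is already on the nozzle) and logs `success=false` — animals are never
silently lost. Optional scheduled feeding pauses all animals for
`feed_duration_s` (60 s) at each interval and logs feed/rinse events;
whether feeding perturbs locomotion beyond the pause is not modeled.

**Random streams.** One seeded generator per animal (plus separate
placement and controller streams), so adding animals never perturbs
existing trajectories, and identical seeds reproduce trajectories, events
and frames bit for bit.

## Analysis pipeline

**Tracking.** Detections are 8-connected components above an intensity
threshold (default 100) with area in [8, 400] px; centroids are
intensity-weighted. Identities are maintained by greedy ascending-distance
one-to-one assignment within a gating radius (3 mm ≈ 6× the per-frame
displacement at 0.5 mm/s and 10 Hz); the animal count is fixed at the first
frame and no identities are created later. A detection larger than 1.6× the
running median single-animal area that gates to two or more tracks is
treated as touching animals: it is shared by all gated tracks with each
centroid frozen at its last offset until separation, and those frames are
flagged `contact`. This freeze-and-flag policy trades positional accuracy
during contact for identity stability; how the real system resolves
contacts is not documented, so this is a declared design choice, not an
inference. Gaps up to `max_gap_frames` (150, comfortably above one
occlusion) are bridged by linear interpolation — exact for linear motion,
and adequate because significant behavior is unlikely within a 10 s gap at
larval speeds.

**Posture.** The midline is the ridge geodesic of the body mask: the
shortest path between the two geodesically farthest pixels with steps
penalized away from the distance-transform ridge, trimmed by the body
half-width at the stadium caps and resampled to 11 points. The bend angle
is 180° minus the interior angle between the chords from the midline
midpoint to the two endpoints (0 = straight); it is invariant under rigid
motion. At ~30-pixel body size, pixel quantization limits bend accuracy to
roughly ±15–20°, which is sufficient for state classification but not for
fine postural analysis. Head/tail assignment normalizes endpoint order by
temporal proximity, then maximizes over the whole series the projection of
the head-to-tail axis onto the smoothed centroid velocity minus a penalty
per orientation flip, solved exactly by a two-state Viterbi pass. Below
`v_min` = 0.05 mm/s the motion evidence is zeroed and the prior orientation
is retained. The default penalty, 3× the median motion-evidence magnitude,
makes a single corrupted frame insufficient to flip the orientation. This
skeleton + momentum + flip-cost construction is a deterministic functional
substitute for learned posture trackers, reproducing their design intents
(temporal context, explicit flip cost), not any particular network.

**Run/turn classification.** A frame is a turn candidate when the smoothed
|heading rate| ≥ 20 deg/s or the smoothed bend ≥ 30°; candidates expand in
both directions while |heading rate| ≥ 10 deg/s or bend ≥ 15° (hysteresis).
Smoothing is a centered 11-frame (1.1 s) boxcar, so labels are a
time-symmetric function of the series: reversing the input reverses the
labels exactly. These thresholds recover ≥ 99% frame agreement and ≈ 95%
of turn events on the default simulator (short runs between near-adjacent
turns merge, biasing the recovered turn rate ~5% low); they are declared
substitutes for a trained state classifier, are config-exposed, and
downstream statistics should always be reported together with them. Turn
segments get a direction and size from the wrapped difference of circular
mean headings over 1 s flanks: counter-clockwise (positive in y-up mm
coordinates) is **left**, the probability-zero 180° tie resolves left, and
turns clipped by the track boundary keep the segment but have
direction/size missing.

**Features.** Speed and heading come from boxcar-smoothed central-difference
velocities (smoothing the derivative rather than the positions keeps
uniform motion unbiased at the track ends); curvature is |dθ/ds| and is
missing below `v_min`. Frames flagged interpolated or contact are
invalidated with an 11-frame margin so manipulation jumps never leak into
summaries. The navigation index is the ratio of means ⟨v_x⟩/⟨v⟩ (not the
mean of per-frame ratios), per 10-min window and overall, over frames above
`v_min`; a runs-only switch is provided, off by default. Population time
courses are 10-min-binned means across animals of within-animal bin means
(the animal is the statistical unit); the activity-decline slope is the
linear fit over the first hour. The peri-event analysis aligns speed to
pick-up/drop-off events in ±5-min windows and t-tests each post-event
minute (per-event minute means; frame samples when only one event exists)
against the pooled pre-event minutes, with no multiple-testing correction —
a deliberate single-comparison usage, flagged here. Trajectory stitching
rigidly translates each post-drop-off sub-path onto the pre-pick-up end
point; path length sums only crawl-frame displacements and is invariant
under the stitching translations.

**Variability.** Observations (e.g. per-window navigation indices) follow a
two-level Gaussian model: per-animal means μᵢ from the inter-animal law —
Gaussian(μ_pop, σ_inter) or, in the bimodal regime, a 50/50 mixture at
μ_pop ± Δ — and observations Gaussian(μᵢ, σ_intra). Defaults (μ_pop = 0.13,
σ_inter = 0.02, σ_intra = 0.1, Δ = 2σ_intra, 40 animals × 360 observations)
put the two regimes robustly on opposite sides of BC_crit. Sarle's
bimodality coefficient uses bias-corrected sample skewness and excess
kurtosis with the finite-sample denominator 3(n−1)²/((n−2)(n−3)); the
asymptotic form (g₁²+1)/(g₂+3) — exactly 5/9 on uniform moments — is
available separately. BC is computed on per-animal mean values (one number
per animal), the unit in which inter-animal multimodality expresses itself;
an all-observations mode is available. Conditions are compared by a
label-permutation null for the p-value and a case-resampling bootstrap over
animals for the ΔBC confidence interval; fewer than 8 animals per condition
raises a small-sample flag, since moment-based BC is unstable at small n.

## What the simulator does and does not emulate

It emulates: the run/turn alternation and its Poisson statistics,
activity decline and plateau, handedness, klinokinetic thermotaxis, robot
transport with retries/occlusions/feeding, dropped frames, and the
sparse-pixel imaging regime (merged blobs when animals touch, quantization
noise). It does **not** emulate: peristaltic body waves, head casts as
distinct sub-behaviors, wall-following, larva–larva interactions beyond
visual merging, sensory adaptation, development between instars, or any
physical robot dynamics. Passing tests therefore certify the analysis
pipeline's correctness on the stated generative model, not its performance
on real video, where posture noise and contact behavior are richer.

## Problem sizes and numerical choices

Validation workloads were sized for single-CPU runs: parameter recovery
uses a 6 h × 5-animal experiment on the trajectory fast path; the
thermotaxis direction check uses 38 animals × 1 h; tracking fidelity uses a
10-min, 2-animal rendered movie in a 60 mm arena (the full 220 mm arena at
0.09 mm/px renders at 2444² px and is supported but unnecessary for
validation); the variability regimes use 100 seeds × 499 permutations.
Ties in identity assignment resolve to the lower animal id; the 180° turn
tie resolves left; NI is missing (never 0) when all frames are below
`v_min`; handedness is missing (never 0) when no directed turns exist; BC
requires n ≥ 4 and nonzero variance. All artifacts embed the config hash
and seed, and reports are byte-identical across reruns of the same config.

## Known limitations

- Bend-angle accuracy is pixel-limited (±15–20° at ~30 px body size).
- The run/turn thresholds are heuristic substitutes for a learned
  classifier; turn-rate estimates are biased ~5% low by merged
  near-adjacent turns.
- Contact frames have degraded positional accuracy by design (frozen
  offsets), and identity through a genuine crossing-in-contact can swap.
- The peri-event t-test treats samples as independent; real speed series
  are autocorrelated, so its p-values are calibrated only under the
  package's noise model.
- The thermal gradient is ideal and static; no PID dynamics or spatial
  nonuniformity is modeled.
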