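# larvatrack

Simulation and analysis of **long-term *Drosophila* larva crawling
behavior**, built around robot-mediated experiments in which a transport arm
returns larvae to the center of a 22 × 22 cm agar arena whenever they near
its edge, enabling continuous multi-hour observation of individual animals.

The package is aimed at quantitative behavior researchers who need the full
chain from raw-style video to per-animal statistics — and a generative model
of the experiment so every stage can be validated against ground truth:

- **synthetic data** — an agent-based run-and-turn random-walk simulator
  (Poisson turn initiation, truncated-Gaussian turn sizes, heading
  diffusion, linearly declining activity), a linear thermal gradient
  (0.035 °C/mm centered at 17 °C), a stochastic edge-triggered pick-up /
  drop-off robot controller with dropped frames during arm occlusion, and a
  sparse-pixel renderer producing ≈30-pixel bright clusters per larva at
  10 Hz;
- **tracking** — blob detection, identity-preserving nearest-neighbour
  linking, gap interpolation across dropped frames, 64 × 64 crop extraction;
- **posture** — midline extraction (distance-transform ridge geodesic),
  body bend angle, and head/tail assignment from centroid momentum with an
  explicit cost for head–tail flips (exact two-state Viterbi);
- **behavior** — per-frame run/turn classification with bidirectional
  hysteresis on heading rate and body bend, and segmentation into labeled
  turns with direction and size;
- **features** — speed, curvature, turn rate, handedness
  (N_left − N_right)/N_total, peri-event transients, trajectory stitching,
  and the thermotaxis **navigation index** NI = ⟨v_x⟩/⟨v⟩ (+1 crawling
  straight up the gradient, −1 straight down, 0 perpendicular);
- **variability** — hierarchical Gaussian observation models, population
  vs mean-of-individual occupancy distributions, and **Sarle's bimodality
  coefficient** BC = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3))) with critical
  value BC_crit = 5/9, plus permutation/bootstrap comparison of BC between
  conditions — separating high intra-animal from high inter-animal
  variability that population averages hide.

## Worked example

Simulate five larvae crawling for one hour on a thermal gradient with the
calibrated klinokinetic gain, then analyze the trajectories end to end:

```python
from larvatrack.config import RunConfig, ThermalField, CALIBRATED_THERMOTAXIS_GAIN
from larvatrack.pipeline import run_pipeline

cfg = RunConfig(n_animals=5, duration_s=3600.0, seed=42, outdir="demo_out")
cfg.thermal = ThermalField(enabled=True)          # 0.035 °C/mm along +x
cfg.locomotion.thermotaxis_gain = CALIBRATED_THERMOTAXIS_GAIN
report = run_pipeline(cfg)
print(report["ni"]["mean"], report["ni"]["p_vs_zero"])
print(report["handedness"]["population"], report["decline_slope_mm_s2"])
```

This prints (seed 42):

```
0.16018158474040338 0.011170579938545854
0.026946107784431138 -6.249573749582113e-05
```

meaning the five simulated animals crawl warm-ward with a mean navigation
index of 0.160 (one-sample t-test against zero, p ≈ 0.011 at only n = 5
animals), show no population turning bias (handedness ≈ 0.03), and their
speed declines over the first hour at −6.2 × 10⁻⁵ mm/s², recovering the
configured decline of −6.9 × 10⁻⁵ mm/s² to within the turn-time fraction.
`demo_out/` contains the trajectory table (CSV), run/turn segment table,
robot-event log (JSON Lines) and the report, all stamped with the config
hash and seed.

The same pipeline is scriptable from the shell:

```bash
larvatrack simulate --seed 42 --n-animals 5 --duration-s 3600 --outdir demo_out
larvatrack analyze --outdir demo_out demo_out/trajectory.csv
larvatrack variability --seed 2 --outdir demo_out
larvatrack run-all --seed 42 --n-animals 5 --duration-s 3600 --outdir demo_out
```

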