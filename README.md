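# smtirf

Single-molecule TIRF analysis of membrane-receptor stoichiometry and
lateral diffusion, with a synthetic movie generator that provides ground
truth for every stage.

## The problem

Total internal reflection fluorescence microscopy (TIRFM) images individual
fluorescent-protein-tagged receptors at the plasma membrane as
diffraction-limited spots. Two classic single-molecule readouts follow:

* **Stoichiometry by photobleaching-step counting.** Each fluorophore in a
  spot bleaches irreversibly in one abrupt step, so the number of downward
  steps in a spot's intensity trace counts its subunits
  (monomer / dimer / trimer / tetramer). This is how ligand-induced
  oligomerization of GPCRs such as the angiotensin II type 1 receptor is
  quantified in fixed cells.
* **Mobility by single-particle tracking.** Linking detections across
  frames gives trajectories; the time-averaged two-dimensional mean square
  displacement at lag *n*·δt,

      MSD(nδt) = 1/(N−1−n) · Σ_{i=1}^{N−1−n} [x((i+n)δt) − x(iδt)]² + [y((i+n)δt) − y(iδt)]²,

  is linear in lag for Brownian motion with slope 4*D*. *D* is estimated by
  ordinary least squares on the first four MSD points (lags capped at
  *n* = 5), and whole tracks are classified free / confined / immobile from
  the moment-scaling-spectrum slope plus a near-zero-*D* floor.

Raw single-molecule movies for such studies are rarely deposited, so this
package pairs the analysis chain with a simulator that emulates the
acquisition regime (160 nm pixels, 100 ms frames, 400-frame fixed-cell
bleaching movies, 10 Hz / 300-frame live-cell tracking series, spot density
below 0.25 /µm², EMCCD-style noise) and records complete ground truth. Every
stage — detection, filtering, trace extraction, step counting, linking, MSD,
classification — is validated by parameter recovery against that truth.

## Pipeline

1. **simulate** — movies (multi-page 16-bit TIFF) or bare traces /
   trajectories with known oligomer mixture, per-fluorophore geometric
   bleaching, and free / confined (reflected at a circular boundary) /
   immobile motion.
2. **detect** — rolling-ball background subtraction (radius 12 px),
   averaging of the first five frames, local-maximum seeding, elliptical 2-D
   Gaussian fits on 5×5 px windows, then the candidate gates: SNR ≥ 3,
   persistence ≥ 5 consecutive frames, pairwise separation ≥ 4 px (both
   members of a close pair are removed), eccentricity
   max(wx, wy)/min(wx, wy) ≤ 1.2.
3. **stoich** — fixed-position intensity traces; slope-only traces excluded
   by a polynomial fit with R² > 0.83 that also outperforms the best step
   model; penalized least-squares change-point segmentation (exact dynamic
   program) with downward-step filtering and step-height quantization;
   monomer–tetramer fractions per cell and pooled.
4. **spt** — global minimum-cost frame-to-frame assignment (max 7 px) with
   gap closing (7 px, ≤ 2 frames); MSD, *D*, motion-mode classification and
   per-mode *D* summaries.
5. **pipeline / CLI** — config-driven, seeded, reproducible runs
   (`smtirf simulate|detect|recover|spt|report`).

## Worked example

Recover a known oligomer mixture from 500 synthetic bleaching traces at a
step-to-noise ratio of 3:

```python
import smtirf as sm

rep = sm.recovery_experiment(
    true_fractions=(0.4016, 0.2891, 0.2042, 0.1051),  # monomer..tetramer
    n_traces=500, seed=0, step_noise_ratio=3.0)
print(rep["estimated_fractions"])   # [0.3665, 0.2940, 0.2464, 0.0932]
print(rep["max_abs_error"])         # 0.0422
print(rep["n_counted"])             # 483  (8 traces never bleached a step)
```

Each recovered fraction lands within ±0.05 of the generating mixture; the
confusion matrix in `rep["confusion_matrix"]` shows where the residual
errors come from (bleach events closer together than the counter's temporal
resolution, and fluorophores surviving the whole movie).

Estimate a diffusion coefficient from 1000 simulated free tracks
(300 frames at 10 Hz, 20 nm localization noise):

```python
import numpy as np
from smtirf.spt import compute_msd, estimate_D

mot = sm.MotionModel("free", D=0.2703, localization_noise_sd=0.02)
paths = sm.sample_trajectories(mot, sm.TRACKING_GEOMETRY, np.zeros((1000, 2)), 0)
D = np.mean([estimate_D(compute_msd(p, 5, 0.1)).D for p in paths])
print(D)   # 0.2708 µm²/s — within 0.2% of the true 0.2703
```

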