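# toadhop

Stereo-videogrammetric analysis of cane-toad (*Rhinella marina*) jumping
trials: camera calibration and 3D reconstruction of snout/cloaca landmark
tracks, standard-plane trajectory alignment, per-hop kinematic variables,
size-corrected morphometrics, raceway-trial summaries, and the comparative
statistics used to contrast range-core and invasion-front cohorts. A
ground-truthed synthetic-data generator (ballistic hops, a simulated
two-camera 240 fps rig, cohort presets with published means and standard
errors) makes every stage of the pipeline verifiable without any video.

## Who this is for

Researchers in animal locomotion and invasion biology who measure jump
kinematics from paired high-speed videos, and anyone who needs a tested,
scriptable replacement for the usual MATLAB digitization/calibration
toolchain downstream of landmark digitization. Landmarks arrive as CSV
tables; the package does everything after that.

## The method

A hop is modelled as point-mass projectile motion of the cloaca,

```
c(t) = c0 + v0 t − ½ g t² e_z ,   g = 981 cm s⁻²,
```

with the snout one body length away along a pitching body axis. Two
cameras (10 cm tripods, 20 cm baseline, 140° between optical axes, 240
fps) are synchronized by a flash spike, calibrated by normalized DLT
resectioning on checkerboard correspondences (views with more than 1%
relative stereo inaccuracy are suppressed), and landmark pairs are
triangulated by homogeneous DLT. Each trajectory is rigidly rotated to the
(x, 0, z) jump plane, and six variables are extracted per hop: mean and
maximum velocity (cm s⁻¹), distance (cm), height (cm), and the signed
elevation of the cloaca→snout axis at take-off and landing (°). Analyses
use each animal's longest hop.

Morphological traits are size-corrected by regressing each linear measure
on snout–vent length (SVL) and keeping the residuals. The statistical
layer provides the fixed-effects nested ANOVA (invasion category +
population nested within category, Type III sums of squares), a
profile-analysis MANOVA of the category × trait interaction (Wilks' Λ),
backward stepwise elimination for multiple regression, and Pearson
correlations — including the link between raceway hop distances and
single-jump performance.

## Worked example

```python
import toadhop as th

rig = th.default_rig(pixel_noise_sd=0.5)             # 240 fps stereo rig
views = th.generate_checkerboard_views(rig, 12, seed=0)
left, right, reports = th.calibrate_rig(views)       # DLT + 1% QC rule

params = th.JumpParams(takeoff_speed=310.0, takeoff_elevation=38.0,
                       body_angle_takeoff=31.78, body_angle_landing=-22.18)
traj, truth = th.simulate_jump(params, rig.fps)
obs, traces = th.render_stereo(traj, rig, seed=0)    # 0.5 px pixel noise
offset = th.estimate_sync_offset(traces["left"], traces["right"])
raw = th.reconstruct_trajectory(obs, left, right, offset, rig.fps)
aligned = th.align_trajectory(raw)
t0, t1 = th.detect_takeoff_landing(aligned)
k = th.extract_kinematics(aligned, t0, t1)
```

prints, via the obvious f-strings:

```
calibration: 12/12 views accepted, resection RMS 2.88e-13 px
planted:   distance 95.1 cm, height 18.6 cm
extracted: distance 95.0 cm, height 18.6 cm, take-off 31.4 deg, landing -22.0 deg
velocities: mean 269 cm/s, max 360 cm/s
```

The planted 95.1 cm hop is recovered to 0.1 cm despite half-pixel image
noise, and the planted body angles (31.78°/−22.18°, the wild-caught
range-core female cohort means) to a few tenths of a degree.

The same stages run from the shell on CSV datasets:

```
toadhop run-all --out-dir pipeline_out --seed 0
toadhop simulate cohort --preset F0/invasion-front/female --out-dir sim --seed 1
```

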