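# fishtrack

Computational core for behavioral tracking of larval zebrafish and
closed-loop visual stimulation: online extraction of tail, eye and
whole-body kinematics from grayscale video, behavior-state estimators
(swim vigor, velocity), closed-loop stimulus-velocity laws, camera↔display
calibration, timed protocol execution with full metadata logging — plus a
synthetic fish-image generator with exact ground truth, used to test every
tracker against known kinematics.

## Modules

| module | what it does |
| --- | --- |
| `fishtrack.imaging` | `Frame` type, preprocessing chain (invert / block-downsample / blur / clip), exponential-moving-average background model, foreground extraction |
| `fishtrack.tail` | head-restrained tail skeletonization (center-of-mass and arc methods), fixed-count resampling, total curvature |
| `fishtrack.eyes` | eye segmentation by thresholding + two largest connected components, moment-based ellipse fit, angle unwrapping |
| `fishtrack.freeswim` | fish detection from background-subtracted frames (eyes + swim bladder landmarks), heading initialization, greedy identity matching, constant-velocity Kalman smoothing, bout kinematics |
| `fishtrack.estimators` | vigor (trailing windowed std of tail curvature), vigor→velocity law, gain-modulated grating velocity, inter-bout intervals, 3-point affine calibration, phototaxis half-field geometry |
| `fishtrack.protocol` | timed stimulus sequencing with exact-rational simulated clock, combiners and conditional stimuli, parameter tree with access audit, CSV/HDF5 logging |
| `fishtrack.synthfish` | ground-truth renderers (tail curves, eye ellipses, swimming scenes, calibration spots) and kinematic generators (bout trains, bout-and-glide trajectories) |

Conventions: pixel coordinates are `(x, y)` = (column, row), origin
top-left; angles in radians from the +x axis. The vigor-derived fish
velocity is *negative* during forward swimming, so a closed-loop grating at
gain 1 slows down while the fish swims.

## CLI

```bash
# render synthetic fixtures (TIFF stack + ground-truth CSV/JSON)
fishtrack simulate --kind scene --seed 1 --out scene/

# track a video (config is TOML or JSON)
fishtrack track tail     --config cfg.toml --video tail.tiff  --out log
fishtrack track eyes     --config cfg.toml --video eyes.tiff  --out log
fishtrack track freeswim --config cfg.toml --video scene.tiff --out log

# execute a timed protocol on the simulated clock
fishtrack run-protocol --config protocol.json --out run/
```

A minimal tail-tracking config:

```toml
[preprocessing]
invert = false
blur_sigma = 1.0
clip_level = 20

[tail]
start_xy = [20, 60]
end_xy = [128, 60]
n_segments = 9
method = "com"   # or "arc"
```

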