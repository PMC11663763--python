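# Methods

This note documents the models implemented in `cinepc`, their assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model

**Closed-form steady state.**  For tissue (T1, T2, density ρ, off-resonance
Δf), protocol (TR, TE, flip angle α) and RF phase increment ψ, with
E1 = e^(−TR/T1), E2 = e^(−TR/T2), φ = 2π·Δf·TR and θ = φ − ψ, the
transverse magnetization sampled at TE is

    M = ρ(1−E1)·sin α · (1 − E2 e^(−iθ))
        / [ (1−E1 cos α)(1−E2 cos θ) − E2(E1−cos α)(E2−cos θ) ]
        · e^(iφ·TE/TR) · e^(−TE/T2).

Sign conventions: positive Δf precesses counterclockwise and θ = φ − ψ, so
ψ = 180° places the on-resonant spin mid-passband and the banding null of
increment ψ sits at Δf = ψ/(360°·TR); nulls of ψ and ψ+180° are exactly
1/(2TR) apart.  The TE factors use the balanced-echo convention (partial
precession φ·TE/TR plus T2 decay); all image-level results in the package
use magnitudes and are insensitive to this phase choice.

**Bloch transient iterator.**  `bloch_transient` iterates the per-TR
recursion (α pulse about an axis whose phase advances by ψ per TR — handled
in the demodulated frame where the axis is fixed and the effective
precession is θ — echo at TE, then relaxation/precession over TR) from
thermal equilibrium, deliberately without an α/2 preparation so that the
transient oscillation is at its worst-case amplitude.  It is the
independent oracle for the closed form: the transient decays with rate
1/T\* = cos²(α/2)/T1 + sin²(α/2)/T2, and the tests run ≈30·T\*/TR
iterations, after which the last echo agrees with the closed form to
better than 1e−5 relative error over a broad (T1, T2, α, Δf, ψ) grid.
A fixed iteration count (e.g. 5·T1/TR) is *not* sufficient when T2 ≈ T1,
which is why the count is tied to T\*.

**Inflow model.**  Flow artifacts are modeled as through-plane plug flow:
at frame f with speed v(f), a spin crosses the slice of thickness d in
n_dwell = max(1, round(d / (v·TR))) TRs, so the voxel holds cohorts that
have experienced 1…n_dwell pulses; its magnitude is the mean of the first
n_dwell transient-echo magnitudes.  Fresh spins near a band carry the
first-echo magnitude ρ·sin α·e^(−TE/T2) — far above the steady-state null —
which reproduces the hyperintense, time-varying, off-resonance-dependent
character of the artifact.  Spins slower than the steady-state settling
time (n_dwell > 5·T1/TR) are treated as stationary.  No partial-volume
ramp or pulsatile in-plane motion is modeled.

## Phantom

Scenes are built from axis-aligned ellipses with literature-typical 3 T
tissue parameters (myocardium T1/T2 ≈ 1200/45 ms, blood 1900/250 ms,
skeletal muscle 1000/40 ms, fat 380/120 ms), a B0 map that is a 2nd-order
polynomial background plus a focal Gaussian gradient, and one or more flow
regions with a pulsatile through-plane waveform (peak ≈ 350 mm/s systolic
for the ventricular preset).  Cardiac motion is a sinusoidal per-frame
scaling of the ellipse axes (≈35% blood-pool contraction at systole), not
an elastic deformation — enough to give the 2D+time network temporal
structure at desk scale.  Noise is Rician, realized as the magnitude of
the clean signal plus complex Gaussian noise with σ = 2% of the reference
peak by default.

The **reference** movie is rendered with every voxel at the mid-passband
(B0 ≡ 0, ψ = 180°) and flow regions stationary and on-resonance,
noise-free: banding- and flow-artifact-free by construction and identical
whatever ψ values are requested.  It is the ground-truth label for
training and for PSNR/SSIM.  An SPC label (registered average of the
120°–240° movies) can be used instead for a more faithful emulation of
labels built from acquired data.

Two presets: `lv_short_axis` (chest wall, myocardial annulus, blood pool,
aorta-like flow region, 150 Hz focal gradient near the heart) and
`la_view` (atrial-like blood pool under a 175 Hz focal gradient, so the
ψ = 180° movie — null at 167.8 Hz for TR 2.98 ms — shows a large-area void
covering ≥25% of the blood-pool ROI, the regime where single-movie
reconstruction has little signal to work from).  Protocol defaults follow
a 3 T cine protocol: TR/TE 2.98/1.37 ms, flip 60°, 24 views per segment
(71.5 ms temporal resolution), two movies of 1 dummy + 5 imaging
heartbeats each (12-heartbeat breath-hold).

**Training corpus.**  `sample_scene` jitters geometry, background field,
focal amplitude/position (|amplitude| 230–320 Hz, sign random with 70%
positive) and flow velocity per seed.  The amplitude range is chosen so
the field inside the heart usually spans both nulls of the 90°/270° pair
(±1/(4TR) ≈ ±84 Hz), i.e. *both* input movies are band-affected — the
regime the twofold method exists for, and the deliberate-unshimmed
condition the combination is meant to survive.  What the generator does
**not** emulate: realistic anatomy, respiratory/elastic motion, coil
sensitivities, k-space sampling and undersampling artifacts, scanner
eddy-current effects.  Passing tests therefore demonstrate correctness of
the mechanisms (band geometry, flow transients, order-invariant fusion,
metric orderings), not in-vivo image quality.

## Classical combinations

Averaging is done on magnitudes, never complex data.  Rigid registration
(used by the SPC label) estimates a single transform per movie — the
misregistration source is a constant breath-hold offset — on the
temporal-mean images by maximizing normalized cross-correlation over
translation (FFT correlation, integer peak, parabolic sub-pixel
refinement; recovery is better than 0.5 px on structured scenes), with an
optional small-rotation grid search that is off by default.  Frames are
resampled with linear interpolation.  Degenerate inputs (constant images,
or a correlation peak with NCC < 0.2, as for unrelated noise images) fall
back to the identity transform with a warning flag rather than an
arbitrary shift.

## Network

`DualEncoderUNet` is a 2D+time U-Net over (t, y, x) with two encoder
branches that are *structurally* shared — the same layer objects process
both inputs, so weight sharing cannot drift.  Per level: two 3×3×3
convolutions with group normalization (largest group count ≤ 8 dividing
the channel width) and ReLU; spatial 2× average pooling between levels;
the temporal dimension is never downsampled.  The two branches' features
are fused by channel concatenation at every level and fed to the decoder
through skip connections (concatenation preserves both branches'
information; the decoder learns the mix).  The final 1×1×1 convolution is
zero-initialized and the output is residual around (p1+p2)/2 with a
non-negativity clamp: the untrained network reproduces the 2P average
baseline exactly, which stabilizes small-scale training and makes
"improvement over the average" the natural evaluation.  Inputs of
arbitrary size are reflect-padded to a multiple of 2^(levels−1) and
cropped back.

The engine is a compact NumPy implementation (explicit forward/backward
per layer, one BLAS matmul per kernel offset for convolutions, Adam
optimizer); it is fully deterministic given the seeds, which the
reproducibility tests rely on.  Defaults: 3 levels, 16 base channels
(≈0.7 M parameters); the desk-scale experiments use 8 base channels
(≈0.18 M parameters), which trains in minutes on one CPU.

**Training.**  Loss is mean absolute error on movies normalized by one
shared factor per pair (99th percentile of the pooled voxels — shared so
the inter-movie intensity relationship that encodes the banding is
preserved).  Batches are random spatiotemporal crops (default 6×32×32),
with flip augmentation and per-sample randomization of the input order
(the stochastic counterpart of symmetrized inference).  Adam at learning
rate 1e−3 for the desk-scale runs (2e−4 is the conservative default in
`TrainConfig`), 900 steps, batch 2.  Validation loss on held-out scenes is
recorded every 50 steps; non-finite losses abort with a diagnostic.

**Desk-scale study conditions** (used by the test suite and
`scripts/acceptance.py`): 26 randomized `lv_short_axis` scenes at
64×64×8 frames, movies at ψ = 90°/270°, 20 scenes for training and 6 held
out.  Reported quantities: mean held-out heart-ROI PSNR of the symmetrized
network output versus the clean reference, compared with the better single
input and the 2P average; and on the `la_view` scene, blood-pool
normalized mean signal and COV for the single 180° movie, the 2P average
and the network.  The expected orderings are directional (network best),
not claims about any in-vivo effect size.

## Metrics

- **PSNR** = 20·log10(L/RMSE) over ROI voxels of all frames, with L the
  reference maximum inside the ROI (reference-anchored and jointly
  scale-invariant with the RMSE); identical movies report `inf`.
- **SSIM**: standard Gaussian-weighted 11×11 window, σ = 1.5, K1 = 0.01,
  K2 = 0.03, dynamic range = reference ROI maximum, computed per frame
  (matching 2D slice-wise evaluation) and averaged over ROI pixels and
  frames.
- **COV**: std/mean over ROI pixels per frame, then averaged across frames
  (pooling all frame-voxels first is a logged alternative).
- **Normalized mean signal**: ROI mean over frames divided by the
  reference's (the phantom reference plays the role an artifact-free
  anatomical scan plays with acquired data).
- **Dice** = 2|A∩B|/(|A|+|B|); two empty masks score 1.0, empty versus
  non-empty 0.0 (continuous at the boundary).
- ROIs need ≥8 pixels; smaller masks raise errors rather than returning
  unstable values.

## Numerical choices and degenerate inputs

- Increments live in (0°, 360°] (ψ_N = 360°) and are compared modulo 360°;
  offsets at exactly 180° are deduplicated to unordered pairs (an
  order-invariant network makes the orderings redundant), which is what
  makes the 12-increment, 54-slice-set corpus come out at 648/324/648.
- Pair enumeration requires uniformly spaced increments and offsets that
  are multiples of the spacing; a single increment yields zero pairs.
- Bloch-oracle comparisons use ≈30·T\*/TR iterations (see above).
- All-zero movie pairs normalize with factor 1 and a warning; empty
  datasets, duplicate ψ lists, wrong SPC increment sets, and geometry
  mismatches raise errors listing the offending values.
- File writes are atomic (temp + rename); cine NIfTIs are (x, y, t) on
  disk, (t, y, x) in memory, float32.

## Known limitations

- The phantom's ellipse anatomy and affine contraction cannot probe
  hallucination behavior, partial-volume effects, or realistic motion;
  conclusions about reader-perceived quality are out of reach by design.
- The inflow model ignores in-plane flow, acceleration and slice-profile
  effects; it reproduces the artifact's character, not any particular
  vessel's appearance.
- Training at desk scale uses small crops and few scenes; the architecture
  is the contribution being exercised, and no attempt is made to reach the
  image quality achievable with large acquired corpora.
- The 1P (single-input) network variant exists only as the degenerate mode
  p2 := p1 of the same model and is not separately tuned.
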