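# cinepc

Desk-scale simulation and reconstruction toolkit for **twofold phase-cycled
bSSFP cardiac cine imaging** with joint suppression of banding and flow
artifacts.

Balanced SSFP (bSSFP) is the workhorse cine sequence in cardiovascular MR,
but its signal has a deep null wherever the off-resonance precession angle
per TR cancels the RF phase increment ψ — dark *banding* artifacts — and
spins flowing through off-resonant regions never reach steady state,
producing hyperintense, time-varying *flow* artifacts.  A twofold
phase-cycled acquisition (2P-SSFP) collects two cine movies with
half-cycle-apart increments (ψ and ψ+180°) in one 12-heartbeat breath-hold;
because the band pattern translates in frequency with ψ, the two movies see
complementary anatomy.  A dual-encoder 2D+time U-Net with shared encoder
weights fuses the pair nonlinearly, and inference is symmetrized over the
input order,

    output(p1, p2) = ( network(p1, p2) + network(p2, p1) ) / 2,

so the reconstruction is order-invariant by construction.  The package is
aimed at sequence/reconstruction researchers who want a self-contained,
physics-grounded testbed for this family of methods: it contains

- `cinepc.protocol` — 2P-SSFP schedule/timing model and training-pair
  combinatorics (ψₙ = 360°·n/N schedules; ordered 90°/270° pairs and
  unordered 180° pairs);
- `cinepc.signal_model` — the closed-form bSSFP steady state, a brute-force
  Bloch transient iterator that serves as its oracle, the through-plane
  inflow model, and band-null bookkeeping;
- `cinepc.phantom` — synthetic phase-cycled short-axis and atrial-view cine
  scenes with ground-truth artifact-free references, B0 field maps, flow
  regions, contraction, and Rician noise;
- `cinepc.combine` — magnitude averaging (the 2P average baseline) and the
  short-range phase-cycling (SPC) label: registration + average of the
  120°/150°/180°/210°/240° movies;
- `cinepc.network` — the dual-encoder network, its NumPy training engine,
  and symmetrized inference;
- `cinepc.metrics` — ROI PSNR/SSIM, coefficient of variation, normalized
  mean signal, and Dice;
- `cinepc.io` / `cinepc.cli` — NIfTI + JSON-sidecar I/O, dataset manifests,
  and the `cinepc` command line (`simulate`, `combine`, `train`, `infer`,
  `eval`, `profile-plot`).

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

```python
import numpy as np
from cinepc import (phase_schedule, enumerate_training_pairs, make_default_scene,
                    render_phase_cycled_cine, average_combine, psnr, cov,
                    normalized_mean_signal, band_null_offset, ScanProtocol)

pairs, counts = enumerate_training_pairs(phase_schedule(12), {90, 180, 270}, 54)
print(f"training pairs: {len(pairs)} total, per offset {counts}")

protocol = ScanProtocol(tr_ms=2.98, te_ms=1.37, flip_deg=60.0)
print(f"banding null for psi=180deg: {band_null_offset(protocol, 180.0):.1f} Hz")

config, protocol = make_default_scene("la_view", grid=(64, 64), n_frames=8)
scene = render_phase_cycled_cine(config, protocol, [90.0, 180.0, 270.0])
roi = scene.masks["blood_pool"]
single = scene.movie(180.0)
avg = average_combine([scene.movie(90.0), scene.movie(270.0)])
for name, movie in [("180deg movie", single), ("2P average", avg)]:
    print(f"{name}: normalized signal "
          f"{normalized_mean_signal(movie, roi, scene.reference):.2f}, "
          f"COV {cov(movie, roi):.2f}, "
          f"heart PSNR {psnr(movie, scene.reference, scene.masks['heart']):.1f} dB")
```

prints

```
training pairs: 1620 total, per offset {90.0: 648, 180.0: 324, 270.0: 648}
banding null for psi=180deg: 167.8 Hz
180deg movie: normalized signal 0.20, COV 0.79, heart PSNR 4.7 dB
2P average: normalized signal 0.80, COV 0.05, heart PSNR 15.3 dB
```

The 12-point schedule yields exactly 1620 training pairs across 54
slice-sets (648 at 90°, 324 unordered at 180°, 648 at 270°).  On the
atrial-view scene a strong focal off-resonance puts the 180°-increment
band right on the blood pool: the movie keeps only 20% of the reference
blood-pool signal with a COV of 0.79, while averaging the 90°/270° pair
recovers 80% of the signal and drops the COV to 0.05.  Training the
dual-encoder network (see `cinepc train --help` or the script below)
pushes signal higher and COV lower still, and on held-out short-axis
scenes its heart-ROI PSNR exceeds both single inputs and the 2P average.

The same pipeline is available from the shell:

```bash
cinepc simulate --preset lv_short_axis --psis 90,270 --seed 7 --n-scenes 20 --out data/
cinepc train    --data data/manifest.json --steps 900 --out model.npz
cinepc infer    --ckpt model.npz --in data/scene_000_psi90.nii.gz data/scene_000_psi270.nii.gz --out net.nii.gz
cinepc eval     --set data/manifest.json --methods average,network --ckpt model.npz --out metrics.csv
```

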