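# coromct — murine coronary micro-CT angiography, in silico

Coronary CT angiography is routine in patients but extraordinarily hard in
mice: the heart beats at up to 600 bpm, the animal breathes at up to
300 rpm, and the left coronary artery tapers from ~400 µm at its ostium
toward ~160 µm — demands that collide with the dose-resolution law of CT
(dose ∝ resolution⁴).  A retrospectively gated micro-CT protocol solves
this by scanning continuously for minutes, deriving cardiac and
respiratory phases *intrinsically* from the projection data, and
reconstructing either phase-correlated volumes

&nbsp;&nbsp;&nbsp;&nbsp;f_Std = X⁻¹ q,&nbsp;&nbsp;&nbsp;&nbsp;f_PC = X⁻¹_PC q

(X the X-ray transform, X⁻¹ filtered backprojection, X⁻¹_PC restricted to
the ~2.5 % of frames inside one joint cardiac×respiratory window) or, to
recover the dose efficiency lost to gating, a motion-compensated volume
f_MoCo: Demons displacement fields between adjacent cardiac phases,
constrained to form a closed loop over the cycle, warp every phase volume
to a reference phase before averaging — so *all* acquired data contribute,
the noise level approaches f_Std, and the temporal resolution stays that
of f_PC.  A structure-tensor adaptive filter (TBAF) further denoises the
result without resolution loss.

`coromct` implements this pipeline end to end for people studying such
reconstruction methods without scanner access: a parametric 4D digital
mouse-heart phantom (the stand-in for the animal), an analytic cone-beam
scanner simulator with Poisson dose scaling, intrinsic gating, FDK / gated
FDK, cyclic Demons motion compensation, TBAF, and quantitative evaluation
(noise, coronary CNR with Rose-criterion detectability, STS-MIP, vessel
tracking, dose sweeps).

## Worked example

Simulate a 30 s desk-scale scan (2,580 frames, 86 fps, 1 s/rev), gate it
intrinsically, and compare the phase-correlated and motion-compensated
reconstructions:

```python
import numpy as np
from coromct import (PhantomSpec, desk_geometry, simulate_scan, apply_noise,
                     extract_gating_signals, GatingSpec, GridSpec,
                     reconstruct_phase_series)
from coromct.gating import end_expiration_bin
from coromct.moco import DemonsParams, estimate_cycle_fields, motion_compensate
from coromct.metrics import phantom_rois, roi_stats, cnr

spec = PhantomSpec(heart_rate=587.0, resp_rate=300.0)
proj = apply_noise(simulate_scan(spec, desk_geometry()), seed=7)

track = extract_gating_signals(proj)
print(f"cardiac {track.cardiac_rate_bpm:.1f} bpm, "
      f"respiratory {track.resp_rate_rpm:.1f} rpm")

gspec = GatingSpec()                      # 4 x 25% resp, 10 x 10% cardiac
grid = GridSpec((72, 72, 72), 0.15)       # 0.15 mm voxels
series = reconstruct_phase_series(proj, track, gspec,
                                  end_expiration_bin(track, gspec), grid)
fields = estimate_cycle_fields(series, DemonsParams(iterations=(30, 20, 10, 5),
                                                    presmooth_sigma=2.0,
                                                    fluid_sigma=2.5,
                                                    diffusion_sigma=1.5))
moco = motion_compensate(series, fields, reference_bin=9)

rois = phantom_rois(spec, grid, cardiac_phase=0.95)
for name, vol in [("PC", series[9]), ("MoCo", moco)]:
    _, sd = roi_stats(vol, rois["myocardium"])
    print(f"{name:4s} myocardial noise {sd:5.0f} HU   "
          f"coronary CNR {cnr(vol, rois['coronary'], rois['myocardium']):.2f}")
```

Output:

```
cardiac 586.8 bpm, respiratory 300.1 rpm
PC   myocardial noise   102 HU   coronary CNR 2.33
MoCo myocardial noise    51 HU   coronary CNR 3.78
```

The intrinsic gating recovers both physiological rates to a fraction of a
percent from the raw projections alone.  The phase-correlated volume uses
only ~2.5 % of the frames and pays for it in noise; motion compensation
restores all frames of the respiratory window to the reference phase,
halving the myocardial noise and lifting the coronary contrast-to-noise
ratio — the same ordering the method shows across a 2000→500 mGy dose
sweep (`coromct.metrics.dose_sweep`).

The same pipeline is scriptable from the shell with per-stage manifests:

```bash
coromct run --seed 1 -o out/          # simulate → gate → recon → moco →
                                      # tbaf → sweep → report
coromct tbaf-volume out/f_moco.nii.gz out/f_moco_tbaf.nii.gz --sigma-g 1.0
```

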