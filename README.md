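# trogopy

Quantitative image analysis of microglia–synapse interactions in 3D
time-lapse fluorescence volumes, with a synthetic-scene simulator that
makes every analysis stage verifiable against scripted ground truth.

Microglia, the brain's resident immune cells, contact dendritic spines and
presynaptic boutons and remove presynaptic material by **trogocytosis** —
partial "nibbling" of sub-µm³ fragments rather than whole-synapse
phagocytosis. Quantifying this from light-sheet time-lapse data (anisotropic
130 nm lateral / 480 nm axial voxels, 45–90 s frames, 2–3 h sessions)
requires a chain of image-analysis steps: noise thresholding, drift
correction, process-skeleton motility analysis, contact classification by
spine-head surface coverage, engulfment-event detection with latency
measurement, per-spine morphometric time series with bootstrap
cross-correlation, spine-head-filopodium (SHF) detection with circular
direction statistics, and EM-style inclusion morphometry. `trogopy`
implements that chain as a tested Python library for researchers analysing
microglia–synapse imaging experiments — and, because no public dataset
accompanies the protocols it implements, ships a first-class phantom
generator whose scripted events are the ground truth every detector is
scored against.

## Core quantities

- **Contact classes** — fraction *f* of spine-head surface voxels within a
  contact distance of the microglia mask: apposition for 0.20 ≤ *f* ≤ 0.50,
  encapsulation for *f* > 0.70 (the gap is reported explicitly as
  "intermediate").
- **Motility** — process tips matched across 1-min intervals (Hungarian
  assignment); extension/retraction events per cell per minute and speeds
  in µm/min.
- **Trogocytosis events** — presynaptic-label components newly appearing
  fully inside the (eroded) microglia mask, continuous with a contacted
  bouton; latency = contact time before internalization.
- **Spine dynamics** — per-frame spine length (geodesic along the
  skeleton), head intensity, contact extent; lagged Pearson
  cross-correlation of contact extent with length variation, with a
  spine-resampling bootstrap (pointwise CIs plus a simultaneous band).
- **Direction statistics** — Anderson–Darling uniformity test of SHF
  angles on [0°, 180°]:
  A² = −n − (1/n)·Σᵢ (2i−1)·[ln uᵢ + ln(1−u₍ₙ₊₁₋ᵢ₎)].
- **Inclusions** — volume-equivalent sphere diameter d = (6V/π)^⅓,
  complete vs partial ("pinched") by containment topology.

Thresholding follows the noise-plus-40% rule throughout: noise is measured
outside the cell and voxels are kept strictly above 1.4× that level.

## Worked example

`examples/motility_analysis.py` builds a synthetic microglia scripted at
the emulated study conditions (26 extension / 21 retraction events per
cell per minute at 1.9 / 1.8 µm/min), renders it noiselessly, and runs the
motility stage:

```
detected 92 extensions, 60 retractions over 3 min
rates: 30.7 ext/min, 20.0 ret/min (scripted 26 and 21)
mean speeds: 1.96 / 1.87 µm/min (scripted 1.9 / 1.8)
```

One 3-minute session carries Poisson counting noise of ±3 events/min;
across 50 replicate cells the recovered means match the scripted rates
within their standard errors. The other scripts in `examples/` demonstrate
session simulation, engulfment detection with latency, spine/SHF dynamics
with the Anderson–Darling test, contact classification, and inclusion
morphometry — each prints the numbers it computes and what they mean.

A thin CLI orchestrates file-based runs
(`trogopy all --config cfg.json`); the importable API is the primary
surface.

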