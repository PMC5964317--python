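# Methods

## The problem and the approach

Microglia–synapse interaction studies quantify, from multi-channel 3D
time-lapse fluorescence volumes, how microglial processes contact
dendritic spines and presynaptic boutons, remove presynaptic material by
trogocytosis, and induce spine head filopodia (SHFs). `trogopy`
implements the full measurement chain and validates every stage against a
synthetic-scene generator: geometric phantoms with scripted events are
rendered through an acquisition model, analysed by the same code a real
dataset would pass through, and scored against the script. No stage is
ever tested only on its own output.

## Acquisition model

Volumes are `(t, channel, z, y, x)` with z the axial axis. Defaults
emulate light-sheet live imaging: 130 nm lateral pixels, 480 nm axial
step, 45–90 s frames, 2–3 h sessions. Rendering is anisotropic Gaussian
blur (default PSF σ 150 nm lateral / 550 nm axial — typical
light-sheet-scale blur; no spatially varying PSF or bleaching), Poisson
photon noise at `photon_scale` expected photons per unit phantom
intensity, then a camera `baseline` (default 100 counts) plus Gaussian
read noise (sd 5). The baseline matters: the noise-plus-40% threshold rule
measures the background level, which on a real detector is the offset,
not zero. `photon_scale` defaults to 500, chosen so that the thinnest
scripted structures (160 nm-radius filopodia) render several σ above the
+40% cutoff — the experiments being emulated treat SHFs as clearly
measurable objects, and a photon budget that renders them invisible would
fail to emulate them. Optional crosstalk adds a fraction of the microglia
occupancy into the neuron channel (residual reporter expression), which
the preprocessing stage removes again.

With `photon_scale = inf`, zero read noise and vanishing PSF the renderer
returns the phantom occupancy exactly; "noiseless" analyses use this
limit.

## Scene generator

The phantom holds a microglia (soma radius 2.5 µm plus radial processes,
tapering-tube radius 0.28 µm), optionally a dendrite (tube radius 0.4 µm)
carrying spines (neck radius 0.1 µm, length 0.6–1.4 µm; head radius
0.25–0.4 µm), and presynaptic axons (radius 0.12 µm, rendered dimmer than
boutons) carrying 0.4 µm boutons. Geometry choices worth noting:

- Motility process directions follow a golden-angle spiral inside an
  elevation band, guaranteeing ~15° pairwise separation so tubes never
  merge away from the soma and each skeleton tip keeps its identity.
- Tube radii below ~250 nm cannot stay 26-connected across the 480 nm
  axial step, so thin structures (necks, filopodia) are scripted
  near-laterally and the scene plane is snapped onto a voxel-center z.
  This mirrors the practical limit of the sampling: oblique sub-voxel
  filopodia are not representable at this axial step.
- Boutons on one axon are kept ≥ 5 µm apart and contact processes
  approach each bouton perpendicular to its axon via a waypoint, so one
  event's geometry cannot put a neighbouring bouton into apparent
  contact.

Event scripting defaults are the emulated study conditions: 26 extension
and 21 retraction events per cell per minute at 1.9 and 1.8 µm/min
(lognormal jitter, σ=0.15; extensions are assigned to tips with headroom
below the length cap and retractions to tips above the floor — a process
at its bound cannot move further that way, and the realized event count
stays unbiased); spine contacts as a Poisson process (2/spine/h) with
gamma-distributed durations (mean 252 s, shape 2); engulfment as
Poisson(1.5 per cell per 3 h) with exponential latency (mean 6 min),
engulfed fraction 0.2–0.6 (partial, 9/11 of events) or 0.7–0.9
("most of the bouton"), material transferred as a step to a bulged
process end 1.5 µm inside the cell with residual always left at the
origin; SHFs on 13/31 of contacted vs 7% of non-contacted spines,
lengths truncated-normal (mean 1.5 µm, sd 0.6, bounds 0.4–3.1 µm),
directions toward the contacting process with 15° jitter, relocation
with probability 5/21 and mean lifetimes 27 (relocating) vs 12 min;
disappearance 3/31 and transient (appear-and-disappear) 4/31 among
contacted spines, never mid-contact; 2.6 pre-existing inclusions per
cell, mutually separated ≥ 1.3 µm so they resolve as distinct puncta.
Every scripted event lands in a ground-truth event log (CSV, unit-suffixed
columns, 0-based frames); identical parameters and seed reproduce the
scene bit-identically.

The engulfment bulge (radius 1.25 µm) deserves a note: "fully inside the
cell" is operationalized as containment in the microglia mask eroded by
one voxel, and with a 480 nm axial step plus 550 nm axial blur, the
swollen process end must reach ±2 z-slices for an internalized blob to
survive that erosion. The bulge is the phagosomal swelling of the
engulfing process end, sized to the sampling reality.

## Analysis stages

**Preprocessing.** Noise is the arithmetic mean (median available) of a
background region; thresholding keeps voxels strictly above 1.4× the
estimate; applying the rule twice equals once. Crosstalk removal zeroes
sub-cutoff neuron-channel voxels inside the microglia mask and never
touches anything else. Drift correction is integer-voxel phase
correlation of each frame against frame 0 (scikit-image); subvoxel
refinement is out of scope. The pipeline's automatic background region is
the sub-1.2×median intensity band, which in sparse-structure volumes is
background to a very good approximation.

**Skeletons and motility.** Masks are skeletonized (scikit-image) into
graphs whose edges carry anisotropic Euclidean step lengths; geodesic
distances come from Dijkstra on that graph. Tips are degree-1 non-root
nodes. Tips are matched across 1-min intervals by Hungarian assignment on
physical tip distance, gated at 3.5 µm — the gate must exceed the largest
plausible per-interval displacement (~3 µm at these speeds), and a 2 µm
gate demonstrably breaks exactly the fastest genuine events. Matched-tip
displacement is the Euclidean tip-to-tip distance (robust to skeleton
rerouting upstream of the tip, exact for near-straight processes), signed
by the change in along-skeleton soma-to-tip length; unmatched new/lost
tips are measured to their branch point, and branch displacements beyond
the gate are discarded as tracking artifacts rather than scored. Events
below 0.26 µm (two lateral voxels) are suppressed as discretization
flicker. Group comparisons: two-way fixed-effects ANOVA (type II sums of
squares via least squares; interaction requires replication) and Welch
t-tests with Welch–Satterthwaite degrees of freedom.

**Contact classification.** Coverage is computed on the head only, in
full 3D, as the fraction of head-surface voxels (6-neighbourhood surface)
within `contact_distance` of the microglia mask by anisotropic distance
transform. The default contact distance of 260 nm (two lateral voxels)
reflects that light microscopy cannot resolve true membrane apposition;
note that a distance below the 480 nm axial step means structure one
z-slice away never registers, so axially dominated geometries should use
≥ 480 nm. Class bounds: [0.20, 0.50] apposition, > 0.70 encapsulation,
(0.50, 0.70] reported explicitly as intermediate, < 0.20 none. Neck
integrity is 26-connectivity of spine to dendrite in the neuron channel.

**Trogocytosis.** Bouton candidates are presynaptic components at the
session start that are not already inside the cell and exceed 0.02 µm³.
Contact intervals close single-frame gaps (dropouts are plausible at
45–90 s frames for events lasting under 3 min). An engulfment event is a
presynaptic component ≥ 0.005 µm³ (below the 0.01–0.05 µm³ inclusion
range, above single-voxel noise) whose voxels all lie in the
one-voxel-eroded microglia mask, that did not overlap presynaptic signal
at the previous frame, does not sit on the (dilated) static frame-0
presynaptic footprint — engulfed material appears at new locations;
components on the footprint are structure flicker — and whose centroid
lies within 3 µm of a bouton contacted at the previous frame. One event
per (bouton, contact interval); latency is frames since that interval's
onset times the frame interval, hence always a nonnegative multiple of
it. Engulfed fraction compares thresholded-mask volumes and is
semi-quantitative on rendered data (blur shrinks small blobs more than
large boutons); on occupancy masks it is exact. Initial inclusions are
components fully inside the cell at frame 0.

**Spine dynamics.** Spine masks come from the thresholded neuron channel
with the dendritic shaft removed as an elliptic cylinder (700 nm lateral,
1800 nm axial — the axial PSF smears the shaft ±~0.9 µm beyond its
radius, and a narrower removal leaves shaft caps that masquerade as
spines); each annotated base point claims its nearest remaining
component. Length is the maximum geodesic distance from the
dendrite-junction node; the head is the thickest region of the mask
(distance-transform ≥ 0.55× peak); head intensity integrates the neuron
channel over it; contact extent is the fraction of head voxels above
threshold in the microglia channel. Contact durations count in-contact
frames times the frame interval. Cross-correlation: per spine, Pearson
correlation of mean-centered contact extent with mean-centered length
(first-difference mode available) at lags −L…L; the profile is the
across-spine mean, with a spine-resampling percentile bootstrap. The
profile carries pointwise 95% CIs per lag *and* a simultaneous sup-norm
95% band; any statement about the profile at all lags jointly (e.g. "the
null profile is flat") must use the band — pointwise intervals cannot
have joint coverage at their nominal level across ~9 lags.

**SHF detection.** Per frame, the spine skeleton's farthest endpoint
beyond the head node is a filopodium candidate when its along-skeleton
distance from the head exceeds 0.4 µm (the minimum scripted length). A
record opens when a candidate appears after ≥ 2 clean frames (one
spurious flicker frame is tolerated in the look-back) and must persist
≥ 2 frames. Reported length is the straight-line distance from the
pre-onset head centroid to the tip — robust to the skeleton's path
through the head blob. Relocation is head-at-tip: the head centroid
(thickest-region centroid) arrives within 0.6 µm of the branch tip after
displacing ≥ 70% of the branch length; because relocation collapses the
branch (the head now sits at its tip), the detector also checks the
frames just after branch disappearance. Lifetime is (offset − onset) ×
frame interval, right-censored at the session end. Direction statistics
test SHF-to-process angles against uniformity on [0°, 180°] with the
Anderson–Darling statistic and the standard asymptotic tail
approximation (Marsaglia's short series); the uniform null encodes "no
directional relation".

**Inclusion morphometry.** 26-connected foreign-label components
intersecting the filled main cell body; a small morphological closing
(2 iterations, 6-neighbourhood) seals channels narrower than ~2 voxels
before cavity filling, because a pinched inclusion is by definition still
open to the outside through its neck. Complete = entirely within the
filled body; partial otherwise. Detached fragments of the cell's own
label inside the body are self-engulfment. Volume is voxel count ×
anisotropic voxel volume; diameter is the volume-equivalent sphere
(max-Feret caliper available behind a flag). The default histogram uses
0.005 µm³ bins over 0–0.1 µm³.

## What the phantoms do and do not show

The generator reproduces the geometry scale, anisotropic sampling, noise
character, and event phenomenology of the emulated experiments, so
passing recovery tests demonstrates that the detectors are calibrated and
unbiased *under those conditions*: tube-like processes with separated
tips, near-lateral thin protrusions, step-like material transfer,
stationary boutons. Real tissue adds curved and crossing processes,
membrane-level contact geometry below the diffraction limit, gradual
transfer kinetics, moving structures, photobleaching and deconvolution
artifacts — none of which are modelled. Recovery results therefore bound
algorithmic error, not biological measurement error.

## Problem sizes and numerics

Validation cohorts: 50 motility replicates (4 frames, 24×224×224 voxels,
noiseless) and 100–200 trogocytosis cells (121 frames at 90 s = a full
3 h session, 14×160×160 voxels, default noise) — large enough that the
recovery bands are a few percent of the scripted values while a full run
stays in the tens of minutes on one core. Rendering caches the blurred
signal per channel whenever a frame repeats the previous frame's
geometry exactly (events are sparse), which is what makes 200-cell
cohorts affordable. Seeds are mandatory everywhere;
identical seeds give bit-identical scenes, renders, and bootstrap
intervals. Degenerate inputs fail loudly: empty masks, disconnected
components, all-zero registration frames, zero-variance correlation
series (excluded with a warning; an all-excluded cohort is an error),
factorial cells with no observations, and unreplicated interactions are
all explicit errors rather than silent numbers.

## Known limitations

- Engulfed-fraction estimates on rendered data are biased low for small
  transfers; treat them as ordinal unless working on occupancy masks.
- Contact distances below the axial step make axially adjacent structure
  invisible to the coverage and contact detectors (by construction).
- SHF detection assumes one filopodium per spine at a time; simultaneous
  multiple SHFs merge into the longest candidate.
- The two-way ANOVA is fixed-effects; repeated-measures designs (same
  cells across timepoints) are approximated, not modelled.
- Drift correction is integer-voxel; subvoxel drift remains as blur.
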