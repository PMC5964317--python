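"""Quantify microglial process motility on a synthetic session.

Skeletonizes the thresholded microglia mask frame by frame, matches
process tips across 1-minute intervals, and reports extension/retraction
rates (events/cell/min) and speeds (µm/min) against the scripted truth.
"""

from trogopy import simulate as sim
from trogopy.motility import detect_motility_events, summarize_motility
from trogopy.preprocess import ThresholdRule, apply_threshold
from trogopy.skeleton import skeletonize

grid = sim.GridSpec(shape=(24, 224, 224), n_frames=4, frame_interval_s=60.0)
scene = sim.build_scene(sim.EventScriptParams(rng_seed=11), grid,
                        sim.SceneLayout(), rng_seed=11)
vol = sim.render_timelapse(scene, sim.AcquisitionModel(
    frame_interval_s=60.0).noiseless(), rng_seed=12)

soma_vox = tuple(int(c / s) for c, s in zip(scene.soma_center_nm,
                                            grid.voxel_spacing_nm))
rule = ThresholdRule(0.0)
skels = [skeletonize(apply_threshold(vol.channel("microglia")[t], rule),
                     grid.voxel_spacing_nm, soma_vox)
         for t in range(grid.n_frames)]

events = []
for t in range(grid.n_frames - 1):
    events += detect_motility_events(skels[t], skels[t + 1], 60.0, onset_frame=t)

minutes = grid.n_frames - 1
summary = summarize_motility(events, minutes)
print(f"detected {summary['n_extension']} extensions, "
      f"{summary['n_retraction']} retractions over {minutes} min")
print(f"rates: {summary['extension_rate_per_min']:.1f} ext/min, "
      f"{summary['retraction_rate_per_min']:.1f} ret/min "
      f"(scripted 26 and 21)")
print(f"mean speeds: {summary['mean_extension_speed_um_min']:.2f} / "
      f"{summary['mean_retraction_speed_um_min']:.2f} µm/min "
      f"(scripted 1.9 / 1.8)")
# Rates are per-cell event counts per minute of observation; speeds are
# tip displacements over the 1-minute matching interval.
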