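"""Build a synthetic microglia-synapse session and write it to disk.

The scene holds a ramified microglia, a spiny dendrite and two presynaptic
axons; interaction events (contacts, engulfment, spine head filopodia) are
scripted from configurable rates and logged as ground truth.
"""

from pathlib import Path

from trogopy import simulate as sim
from trogopy.io import write_stack
from trogopy.simulate import write_ground_truth

out = Path("scratch/example_session")
out.mkdir(parents=True, exist_ok=True)

grid = sim.GridSpec(shape=(12, 224, 176), n_frames=8, frame_interval_s=90.0)
layout = sim.SceneLayout(
    n_motility_processes=10, n_spines=4, n_axons=2,
    process_length_range_um=(3.0, 5.0), process_length_bounds_um=(2.0, 5.5),
)
params = sim.EventScriptParams(rng_seed=7, contact_rate_per_spine_per_hour=4.0)

scene = sim.build_scene(params, grid, layout, rng_seed=7)
vol = sim.render_timelapse(scene, sim.AcquisitionModel(), rng_seed=8)
write_stack(vol, out / "timelapse.tif")
write_ground_truth(scene.events, out / "ground_truth.csv")

counts = scene.events.table["event_type"].value_counts().to_dict()
print(f"rendered {vol.data.shape} stack (t, channel, z, y, x) to {out}")
print("scripted ground-truth events:", counts)
# Each key is an interaction type; e.g. 'contact' rows carry the scripted
# onset/offset frames that the detectors are later scored against.
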