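import numpy as np
import pytest

from trogopy import simulate as sim

SPACING = (480.0, 130.0, 130.0)


@pytest.fixture(scope="session")
def spacing():
    return SPACING


def make_sphere_mask(shape, center_vox, radius_nm, spacing=SPACING):
    """Digitized sphere: voxel centers within radius of the center point."""
    spacing = np.asarray(spacing, dtype=float)
    center = (np.asarray(center_vox) + 0.5) * spacing
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) * spacing + spacing / 2
    return np.linalg.norm(pts - center, axis=-1) <= radius_nm


@pytest.fixture(scope="session")
def motility_scene():
    """One noiseless motility session: 4 frames, 1 min apart."""
    grid = sim.GridSpec(shape=(24, 224, 224), voxel_spacing_nm=SPACING,
                        n_frames=4, frame_interval_s=60.0)
    scene = sim.build_scene(sim.EventScriptParams(rng_seed=11), grid,
                            sim.SceneLayout(), rng_seed=11)
    return grid, scene


@pytest.fixture(scope="session")
def trogo_session():
    """One rendered 3-h engulfment session with default acquisition noise."""
    from trogopy import preprocess as pp

    grid = sim.GridSpec(shape=(14, 160, 160), voxel_spacing_nm=SPACING,
                        n_frames=120, frame_interval_s=90.0)
    layout = sim.SceneLayout(n_motility_processes=0, n_axons=2)
    scene = sim.build_scene(sim.EventScriptParams(rng_seed=4), grid, layout,
                            rng_seed=4)
    vol = sim.render_timelapse(scene, sim.AcquisitionModel(frame_interval_s=90.0),
                               rng_seed=10004)
    masks = {}
    for ch in ("microglia", "presynaptic"):
        fr = vol.channel(ch)[0]
        rule = pp.ThresholdRule(pp.estimate_noise(fr, fr <= 1.2 * np.median(fr)))
        masks[ch] = np.stack(
            [pp.apply_threshold(vol.channel(ch)[t], rule) for t in range(grid.n_frames)]
        )
    return grid, scene, vol, masks


@pytest.fixture(scope="session")
def spine_scene():
    """Noiseless spine scene rich in contacts and SHFs."""
    grid = sim.GridSpec(shape=(14, 192, 192), voxel_spacing_nm=SPACING,
                        n_frames=40, frame_interval_s=60.0)
    layout = sim.SceneLayout(n_motility_processes=0, n_spines=6)
    params = sim.EventScriptParams(
        rng_seed=7, contact_rate_per_spine_per_hour=3.0,
        shf_probability_contacted=0.8, shf_relocation_probability=0.3,
    )
    scene = sim.build_scene(params, grid, layout, rng_seed=7)
    neuron = np.stack([scene.mask_frame(t, "neuron") for t in range(grid.n_frames)])
    microglia = np.stack(
        [scene.mask_frame(t, "microglia") for t in range(grid.n_frames)]
    )
    return grid, scene, neuron, microglia
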