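"""Simulator ground truth: determinism, rate calibration, rendering physics."""

import numpy as np
import pytest
from scipy import stats

from trogopy import simulate as sim

SPACING = (480.0, 130.0, 130.0)


def _quiet_params(**kw):
    base = dict(
        contact_rate_per_spine_per_hour=0.0,
        engulfment_rate_per_cell_per_3h=0.0,
        bouton_contact_rate_per_cell_per_3h=0.0,
        initial_inclusions_mean=0.0,
        shf_probability_contacted=0.0,
        shf_probability_noncontacted=0.0,
        disappearance_probability_contacted=0.0,
        transient_probability_contacted=0.0,
        stretch_probability_contacted=0.0,
        extension_event_rate_per_min=0.0,
        retraction_event_rate_per_min=0.0,
    )
    base.update(kw)
    return sim.EventScriptParams(**base)


class TestBuildScene:
    def test_zero_rates_give_empty_log(self):
        grid = sim.GridSpec(shape=(12, 224, 160), n_frames=6, frame_interval_s=90)
        layout = sim.SceneLayout(n_motility_processes=8, n_spines=4, n_axons=2,
                                 process_length_range_um=(3, 5),
                                 process_length_bounds_um=(2, 5.5))
        scene = sim.build_scene(_quiet_params(rng_seed=1), grid, layout)
        assert len(scene.events) == 0

    def test_seed_determinism(self):
        grid = sim.GridSpec(shape=(12, 224, 160), n_frames=6, frame_interval_s=90)
        layout = sim.SceneLayout(n_motility_processes=8, n_spines=3, n_axons=2,
                                 process_length_range_um=(3, 5),
                                 process_length_bounds_um=(2, 5.5))
        params = sim.EventScriptParams(rng_seed=42)
        a = sim.build_scene(params, grid, layout, rng_seed=42)
        b = sim.build_scene(params, grid, layout, rng_seed=42)
        assert a.signature() == b.signature()
        assert a.events.equals(b.events)
        c = sim.build_scene(params, grid, layout, rng_seed=43)
        assert not a.events.equals(c.events) or a.signature() != c.signature()

    def test_grid_too_small_names_extent(self):
        grid = sim.GridSpec(shape=(8, 64, 64), n_frames=2, frame_interval_s=90)
        with pytest.raises(sim.SceneSizeError, match="20 µm"):
            sim.build_scene(sim.EventScriptParams(), grid, sim.SceneLayout())

    def test_process_reach_checked_against_grid(self):
        grid = sim.GridSpec(shape=(12, 160, 160), n_frames=2, frame_interval_s=90)
        with pytest.raises(sim.SceneSizeError, match="reach"):
            sim.build_scene(sim.EventScriptParams(), grid,
                            sim.SceneLayout(process_length_bounds_um=(3, 15)))

    def test_engulfment_poisson_mean_over_replicates(self):
        """Scripted engulfment counts are Poisson with the configured mean."""
        grid = sim.GridSpec(shape=(14, 160, 160), n_frames=121,
                            frame_interval_s=90)
        layout = sim.SceneLayout(n_motility_processes=0, n_axons=2,
                                 boutons_per_axon=4)
        counts = []
        for seed in range(200):
            params = _quiet_params(engulfment_rate_per_cell_per_3h=2.0,
                                   rng_seed=seed)
            scene = sim.build_scene(params, grid, layout)
            counts.append(len(scene.events.of_type("engulfment")))
        counts = np.asarray(counts)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 2.0) < 3 * se
        # chi-square goodness of fit against Poisson(2), alpha = 0.01
        kmax = 6
        obs = np.array([(counts == k).sum() for k in range(kmax)]
                       + [(counts >= kmax).sum()])
        pk = stats.poisson.pmf(np.arange(kmax), 2.0)
        exp = np.append(pk, 1 - pk.sum()) * len(counts)
        _, p = stats.chisquare(obs, exp)
        assert p > 0.01

    def test_shf_lengths_within_bounds(self):
        grid = sim.GridSpec(shape=(14, 192, 192), n_frames=40, frame_interval_s=60)
        layout = sim.SceneLayout(n_motility_processes=0, n_spines=6)
        lengths = []
        for seed in range(12):
            params = sim.EventScriptParams(rng_seed=seed,
                                           shf_probability_contacted=1.0,
                                           contact_rate_per_spine_per_hour=3.0)
            scene = sim.build_scene(params, grid, layout)
            shf = scene.events.of_type("shf")
            if len(shf):
                lengths.extend(shf["length_um"].tolist())
        assert lengths
        assert min(lengths) >= 0.4 and max(lengths) <= 3.1

    def test_every_scripted_event_has_valid_frames(self, motility_scene):
        grid, scene = motility_scene
        t = scene.events.table
        assert (t["onset_frame"] <= t["offset_frame"]).all()
        assert (t["offset_frame"] <= grid.n_frames).all()


class TestRender:
    def test_noiseless_limit_equals_occupancy(self):
        grid = sim.GridSpec(shape=(12, 160, 160), n_frames=2, frame_interval_s=90)
        layout = sim.SceneLayout(n_motility_processes=6, n_axons=0,
                                 process_length_range_um=(3, 5),
                                 process_length_bounds_um=(2, 6.5))
        scene = sim.build_scene(_quiet_params(rng_seed=2), grid, layout)
        acq = sim.AcquisitionModel(frame_interval_s=90).noiseless()
        vol = sim.render_timelapse(scene, acq, rng_seed=0)
        occ = scene.rasterize_frame(0)["microglia"]
        np.testing.assert_allclose(vol.channel("microglia")[0], occ, atol=1e-5)

    def test_empty_scene_is_baseline_noise_only(self):
        grid = sim.GridSpec(shape=(12, 160, 160), n_frames=2, frame_interval_s=90)
        scene = sim.ScenePhantom(grid, sim.SceneLayout(), ("microglia",))
        acq = sim.AcquisitionModel(frame_interval_s=90)
        vol = sim.render_timelapse(scene, acq, rng_seed=1)
        assert abs(vol.data.mean() - acq.baseline) < 1.0

    def test_blur_conserves_mass_within_one_percent(self):
        """A 500 nm sphere blurred by the PSF keeps its integrated intensity."""
        grid = sim.GridSpec(shape=(24, 160, 160), n_frames=1, frame_interval_s=90)
        scene = sim.ScenePhantom(grid, sim.SceneLayout(), ("microglia",))
        scene.add(0, "microglia", ("sphere", grid.center_nm, 500.0, 1.0))
        acq = sim.AcquisitionModel(
            frame_interval_s=90, photon_scale=float("inf"), read_noise_sd=0.0,
            baseline=0.0,
        )
        vol = sim.render_timelapse(scene, acq, rng_seed=0)
        blurred = float(vol.channel("microglia")[0].sum())
        raw = float(scene.rasterize_frame(0)["microglia"].sum())
        assert abs(blurred - raw) / raw < 0.01

    def test_crosstalk_bleeds_microglia_into_neuron_channel(self):
        grid = sim.GridSpec(shape=(12, 192, 192), n_frames=1, frame_interval_s=90)
        layout = sim.SceneLayout(n_motility_processes=0, n_spines=2)
        scene = sim.build_scene(_quiet_params(rng_seed=3), grid, layout)
        clean = sim.render_timelapse(
            scene, sim.AcquisitionModel(frame_interval_s=90).noiseless(), 0
        )
        acq = sim.AcquisitionModel(frame_interval_s=90, crosstalk_fraction=0.3,
                                   photon_scale=float("inf"), read_noise_sd=0.0,
                                   baseline=0.0, psf_sigma_nm=(1e-6, 1e-6))
        bled = sim.render_timelapse(scene, acq, 0)
        mg = scene.mask_frame(0, "microglia")
        neuron_occ = scene.rasterize_frame(0)["neuron"]
        inside = mg & (neuron_occ == 0)
        assert np.allclose(bled.channel("neuron")[0][inside], 0.3, atol=1e-5)
        assert np.allclose(clean.channel("neuron")[0][inside], 0.0, atol=1e-5)

    def test_spacing_mismatch_rejected(self):
        grid = sim.GridSpec(shape=(12, 160, 160), n_frames=1, frame_interval_s=90)
        scene = sim.ScenePhantom(grid, sim.SceneLayout(), ("microglia",))
        acq = sim.AcquisitionModel(voxel_spacing_nm=(300, 100, 100),
                                   frame_interval_s=90)
        with pytest.raises(ValueError, match="spacing"):
            sim.render_timelapse(scene, acq, 0)

    def test_nonpositive_psf_rejected(self):
        with pytest.raises(ValueError, match="psf"):
            sim.AcquisitionModel(psf_sigma_nm=(0.0, 150.0))

    def test_render_determinism(self):
        grid = sim.GridSpec(shape=(12, 160, 160), n_frames=2, frame_interval_s=90)
        layout = sim.SceneLayout(n_motility_processes=4, n_axons=0,
                                 process_length_range_um=(3, 5),
                                 process_length_bounds_um=(2, 6.5))
        scene = sim.build_scene(_quiet_params(rng_seed=5), grid, layout)
        acq = sim.AcquisitionModel(frame_interval_s=90)
        a = sim.render_timelapse(scene, acq, rng_seed=9)
        b = sim.render_timelapse(scene, acq, rng_seed=9)
        np.testing.assert_array_equal(a.data, b.data)


def test_ground_truth_round_trip(tmp_path, motility_scene):
    from trogopy.events import read_events

    _, scene = motility_scene
    sim.write_ground_truth(scene.events, tmp_path / "gt.csv")
    back = read_events(tmp_path / "gt.csv")
    assert scene.events.equals(back)
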