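"""Spine morphometrics, cross-correlation, SHF detection, direction stats."""

import math

import numpy as np
import pytest

from trogopy import spines as sp
from conftest import SPACING

SPACING_T = SPACING


def _straight_spine_masks(n_frames=3, n_vox=11, shape=(5, 12, 30)):
    """Spine of n_vox voxels along x at 130 nm; base at x=4."""
    mask = np.zeros(shape, bool)
    mask[2, 6, 4:4 + n_vox] = True
    return np.stack([mask] * n_frames)


class TestSpineMetrics:
    def test_straight_spine_length(self):
        """11 voxels along x: 10 gaps of 0.13 µm -> length 1.3 µm."""
        masks = _straight_spine_masks()
        dend = np.zeros(masks.shape[1:], bool)
        dend[2, 6, :4] = True
        neuron = np.where(masks, 500.0, 0.0)
        microglia = np.zeros_like(neuron)
        tr = sp.spine_metrics(masks, dend, neuron, microglia, 140.0, SPACING_T,
                              base_vox=(2, 6, 4))
        assert tr.length_um == pytest.approx([1.3] * 3, abs=0.01)

    def test_no_microglia_means_zero_contact_extent(self):
        masks = _straight_spine_masks()
        neuron = np.where(masks, 500.0, 0.0)
        tr = sp.spine_metrics(masks, masks[0] * False, neuron,
                              np.zeros_like(neuron), 140.0, SPACING_T,
                              base_vox=(2, 6, 4))
        assert (tr.contact_extent == 0).all()

    def test_full_overlap_means_extent_one(self):
        masks = _straight_spine_masks()
        neuron = np.where(masks, 500.0, 0.0)
        microglia = np.full_like(neuron, 300.0)
        tr = sp.spine_metrics(masks, masks[0] * False, neuron, microglia,
                              140.0, SPACING_T, base_vox=(2, 6, 4))
        assert (tr.contact_extent == 1.0).all()

    def test_mid_session_gap_is_tracking_error(self):
        masks = _straight_spine_masks(n_frames=5)
        masks[2] = False
        with pytest.raises(ValueError, match="disappearance"):
            sp.spine_metrics(masks, masks[0] * False,
                             np.where(masks, 500.0, 0.0),
                             np.zeros(masks.shape, float), 140.0, SPACING_T,
                             base_vox=(2, 6, 4))


def _track(spine_id, extent, length, head=None):
    n = len(extent)
    return sp.SpineTrack(
        spine_id=spine_id, frames=np.arange(n),
        length_um=np.asarray(length, float),
        head_intensity=np.asarray(head if head is not None else np.ones(n)),
        contact_extent=np.asarray(extent, float),
    )


class TestFatesAndDurations:
    def test_fate_classification(self):
        n = 30
        stable = _track("s", np.zeros(n), np.ones(n))
        gone = _track("d", np.zeros(20), np.ones(20))
        gone.disappeared_frame = 20
        trans = _track("t", np.zeros(10), np.ones(10))
        trans.frames = np.arange(10, 20)
        trans.appeared_frame = 10
        trans.disappeared_frame = 20
        fates = sp.classify_spine_fates([stable, gone, trans], n)
        assert dict(zip(fates["spine_id"], fates["fate"])) == {
            "s": "stable", "d": "disappeared", "t": "transient"}

    def test_contact_durations_three_frames_at_60s(self):
        """Contact on frames 3-5 at 60 s frames is a 3 min contact."""
        extent = np.zeros(10)
        extent[3:6] = 0.5
        durs = sp.contact_durations([_track("a", extent, np.ones(10))], 60.0)
        assert len(durs) == 1
        assert durs.iloc[0]["duration_min"] == pytest.approx(3.0)
        assert durs.iloc[0]["onset_frame"] == 3

    def test_no_contact_no_rows(self):
        durs = sp.contact_durations([_track("a", np.zeros(8), np.ones(8))], 60.0)
        assert len(durs) == 0

    def test_recontacts_counted_per_spine(self):
        extent = np.zeros(12)
        extent[2:4] = 0.5
        extent[8:10] = 0.5
        durs = sp.contact_durations([_track("a", extent, np.ones(12))], 60.0)
        assert len(durs) == 2
        assert (durs["n_contacts_for_spine"] == 2).all()

    def test_scripted_duration_mean_recovered(self):
        """100 gamma-scripted contacts at mean 4.2 min recovered within 3 SE."""
        rng = np.random.default_rng(3)
        interval = 60.0
        tracks = []
        scripted = []
        for i in range(100):
            dur_f = max(1, round(rng.gamma(2.0, 252.0 / 2.0) / interval))
            n = dur_f + 20
            extent = np.zeros(n)
            extent[5:5 + dur_f] = 0.6
            scripted.append(dur_f * interval / 60.0)
            tracks.append(_track(i, extent, np.ones(n)))
        durs = sp.contact_durations(tracks, interval)
        assert durs["duration_min"].mean() == pytest.approx(np.mean(scripted),
                                                            abs=1e-9)
        se = np.std(scripted, ddof=1) / 10.0
        assert abs(durs["duration_min"].mean() - 4.2) < max(3 * se, 0.75)

    def test_neighbor_selection_within_4um(self):
        positions = {"a": 0.0, "b": 2.5, "c": 9.0}
        contacted = {"a": True, "b": False, "c": False}
        assert sp.noncontacted_neighbors(positions, contacted) == ["b"]


class TestCrossCorrelation:
    def _shifted_tracks(self, lag=2, n_tracks=6, n=60, seed=0):
        rng = np.random.default_rng(seed)
        tracks = []
        for i in range(n_tracks):
            x = rng.normal(size=n + abs(lag))
            contact = x[:n]
            length = np.roll(x, lag)[:n]  # length(t) = contact(t - lag)
            tracks.append(_track(i, (contact - contact.min()) /
                                 np.ptp(contact), length + 5))
        return tracks

    def test_peak_at_injected_lag(self):
        prof = sp.cross_correlate(self._shifted_tracks(lag=2), max_lag=5,
                                  n_boot=200, rng_seed=1)
        assert prof.lags[int(np.argmax(prof.mean_r))] == 2
        assert prof.mean_r.max() > 0.8

    def test_self_correlation_is_one_at_lag_zero(self):
        rng = np.random.default_rng(4)
        tracks = []
        for i in range(3):
            x = rng.normal(size=40)
            tracks.append(_track(i, (x - x.min()) / np.ptp(x), x - x.min()))
        prof = sp.cross_correlate(tracks, max_lag=3, n_boot=50, rng_seed=0)
        assert prof.mean_r[prof.lags.tolist().index(0)] == pytest.approx(1.0)

    def test_white_noise_ci_covers_zero(self):
        """The simultaneous 95% band covers 0 at all lags in >= 90% of runs.

        A statement about all lags jointly needs the simultaneous band;
        pointwise intervals cannot have joint coverage at this level.
        """
        rng = np.random.default_rng(8)
        good = 0
        n_runs = 20
        for run in range(n_runs):
            tracks = []
            for i in range(13):   # cohort size of the emulated experiment
                tracks.append(_track(i, rng.uniform(size=60),
                                     rng.uniform(1.0, 2.0, size=60)))
            prof = sp.cross_correlate(tracks, max_lag=4, n_boot=400,
                                      rng_seed=run)
            if ((prof.band_lo <= 0) & (prof.band_hi >= 0)).all():
                good += 1
        assert good >= 0.9 * n_runs

    def test_fewer_than_three_tracks_rejected(self):
        with pytest.raises(ValueError, match="3 spine"):
            sp.cross_correlate(self._shifted_tracks()[:1], max_lag=2)

    def test_constant_series_excluded_with_warning(self):
        tracks = self._shifted_tracks(n_tracks=3)
        tracks.append(_track("flat", np.zeros(60), np.ones(60)))
        with pytest.warns(UserWarning, match="constant"):
            prof = sp.cross_correlate(tracks, max_lag=3, n_boot=50, rng_seed=0)
        assert prof.per_spine_r.shape[0] == 3

    def test_ci_contains_mean(self):
        prof = sp.cross_correlate(self._shifted_tracks(), max_lag=4,
                                  n_boot=300, rng_seed=2)
        assert ((prof.ci_lo <= prof.mean_r + 1e-9)
                & (prof.mean_r - 1e-9 <= prof.ci_hi)).all()


class TestAndersonDarling:
    def test_three_point_oracle(self):
        """u = {0.25, 0.5, 0.75} gives A2 = 0.2694 by direct evaluation."""
        a2, p = sp.anderson_darling_uniform([45.0, 90.0, 135.0])
        assert a2 == pytest.approx(0.26938, abs=1e-4)
        assert p > 0.5

    def test_brute_force_sum_for_all_small_n(self):
        rng = np.random.default_rng(6)
        for n in range(3, 9):
            for _ in range(20):
                u = np.sort(rng.uniform(0.02, 0.98, size=n))
                angles = u * 180.0
                a2, _ = sp.anderson_darling_uniform(angles)
                total = 0.0
                for i in range(1, n + 1):
                    total += (2 * i - 1) * (
                        math.log(u[i - 1]) + math.log(1 - u[n - i])
                    )
                oracle = -n - total / n
                assert a2 == pytest.approx(oracle, rel=1e-12)

    def test_concentrated_angles_reject_uniformity(self):
        angles = np.full(21, 1e-3)
        a2, p = sp.anderson_darling_uniform(angles)
        assert a2 > 10 and p < 0.001

    def test_uniform_quantiles_below_critical_value(self):
        n = 100
        angles = (np.arange(1, n + 1) - 0.5) / n * 180.0
        a2, p = sp.anderson_darling_uniform(angles)
        assert a2 < 2.492  # 5% critical value of the limiting distribution
        assert p > 0.05

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError):
            sp.anderson_darling_uniform([10.0, 190.0, 20.0])

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            sp.anderson_darling_uniform([10.0, 20.0])


class TestSHFOnScene:
    def test_scripted_shf_recovered(self, spine_scene):
        """Noiseless scene: every scripted SHF >= 0.6 µm is found with the
        right onset, length within 15%, and relocation status."""
        grid, scene, neuron_masks, _ = spine_scene
        masks = sp.extract_spine_masks(
            neuron_masks, scene.dendrite_axis_nm,
            [s.base_point_nm for s in scene.spines], grid.voxel_spacing_nm,
        )
        found, total = 0, 0
        for j, spm in masks.items():
            spec = scene.spines[j]
            if not spm.any():
                continue
            base_vox = tuple(int(c / s) for c, s in
                             zip(spec.base_point_nm, grid.voxel_spacing_nm))
            recs = sp.detect_shf(spm, grid.voxel_spacing_nm,
                                 grid.frame_interval_s, base_vox, spine_id=j,
                                 microglia_direction=(0, 1, 0))
            if spec.shf and spec.shf.length_nm >= 600:
                total += 1
                hit = [r for r in recs
                       if abs(r.onset_frame - spec.shf.onset_frame) <= 1]
                if hit:
                    found += 1
                    assert hit[0].max_length_um == pytest.approx(
                        spec.shf.length_nm / 1000.0, rel=0.15)
                    assert hit[0].relocated == spec.shf.relocates
                    assert hit[0].angle_to_microglia_deg < 45.0
        assert total >= 2
        assert found == total

    def test_no_new_branch_no_records(self):
        masks = _straight_spine_masks(n_frames=6)
        recs = sp.detect_shf(masks, SPACING_T, 60.0, (2, 6, 4))
        assert recs == []


class TestSummaries:
    def test_four_of_31_transient_is_12_9_percent(self):
        import pandas as pd

        rows = []
        for i in range(31):
            rows.append({"spine_id": i, "fate": "transient" if i < 4 else "stable",
                        "contacted": True})
        for i in range(31, 59):
            rows.append({"spine_id": i, "fate": "stable", "contacted": False})
        fates = pd.DataFrame(rows)
        out = sp.summarize_spine_events(fates, shf_spines=set())
        contacted = out[out["group"] == "contacted"].iloc[0]
        assert contacted["transient_percent"] == 12.9
        assert round(contacted["transient_percent"]) == 13

    def test_three_of_31_disappeared_is_9_7_percent(self):
        import pandas as pd

        rows = [{"spine_id": i,
                 "fate": "disappeared" if i < 3 else "stable",
                 "contacted": True} for i in range(31)]
        rows += [{"spine_id": 100 + i, "fate": "stable", "contacted": False}
                 for i in range(28)]
        out = sp.summarize_spine_events(pd.DataFrame(rows), shf_spines=set())
        contacted = out[out["group"] == "contacted"].iloc[0]
        assert contacted["disappeared_percent"] == 9.7
        assert round(contacted["disappeared_percent"]) == 10

    def test_zero_shf_in_noncontacted_group(self):
        import pandas as pd

        rows = [{"spine_id": i, "fate": "stable", "contacted": i < 5}
                for i in range(10)]
        out = sp.summarize_spine_events(pd.DataFrame(rows),
                                        shf_spines={0, 1})
        non = out[out["group"] == "non_contacted"].iloc[0]
        assert non["shf_percent"] == 0.0

    def test_empty_group_rejected(self):
        import pandas as pd

        rows = [{"spine_id": 0, "fate": "stable", "contacted": True}]
        with pytest.raises(ValueError, match="empty group"):
            sp.summarize_spine_events(pd.DataFrame(rows), shf_spines=set())


class TestSHFLifetimes:
    def _rec(self, lifetime, relocated):
        return sp.SHFRecord(0, 0, 0, 1.0, (0, 1, 0), 10.0, relocated, lifetime)

    def test_scripted_27_vs_12_minutes_recovered(self):
        recs = [self._rec(27.0, True) for _ in range(5)]
        recs += [self._rec(12.0, False) for _ in range(16)]
        out = sp.compare_shf_lifetimes(recs)
        assert out["relocating"]["mean_min"] == pytest.approx(27.0)
        assert out["non_relocating"]["mean_min"] == pytest.approx(12.0)
        assert out["relocating"]["n"] == 5

    def test_equal_lifetimes_equal_means(self):
        recs = [self._rec(10.0, True), self._rec(10.0, False)]
        out = sp.compare_shf_lifetimes(recs)
        assert out["relocating"]["mean_min"] == out["non_relocating"]["mean_min"]

    def test_single_record_group_has_no_sem(self):
        out = sp.compare_shf_lifetimes([self._rec(8.0, True),
                                        self._rec(5.0, False),
                                        self._rec(7.0, False)])
        assert out["relocating"]["sem_min"] is None

    def test_missing_group_reported_as_missing(self):
        out = sp.compare_shf_lifetimes([self._rec(8.0, False)])
        assert out["relocating"]["mean_min"] is None
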