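"""Engulfment detection: contact intervals, latency, inclusions, groups."""

import numpy as np
import pandas as pd
import pytest

from trogopy import trogocytosis as tg
from conftest import SPACING, make_sphere_mask

SHAPE = (10, 40, 40)


def _bouton_labels(center=(5, 20, 30), radius=400):
    mask = make_sphere_mask(SHAPE, center, radius)
    return np.where(mask, 1, 0)


def _microglia_run(contact_frames, n_frames=12, center=(5, 20, 10), reach=(5, 20, 27)):
    """Microglia blob that extends a tube toward the bouton on given frames."""
    masks = []
    for t in range(n_frames):
        m = make_sphere_mask(SHAPE, center, 900)
        if t in contact_frames:
            m |= make_sphere_mask(SHAPE, reach, 600)
        masks.append(m)
    return np.stack(masks)


class TestContacts:
    def test_never_adjacent_bouton_empty_intervals(self):
        labels = _bouton_labels()
        mg = _microglia_run(contact_frames=set())
        out = tg.detect_bouton_contacts(labels, mg, SPACING)
        assert out[1] == []

    def test_scripted_frames_4_to_9_one_interval(self):
        labels = _bouton_labels()
        mg = _microglia_run(contact_frames=set(range(4, 10)))
        out = tg.detect_bouton_contacts(labels, mg, SPACING)
        assert out[1] == [(4, 9)]

    def test_single_frame_gap_closed(self):
        labels = _bouton_labels()
        mg = _microglia_run(contact_frames={4, 5, 7, 8})  # dropout at 6
        out = tg.detect_bouton_contacts(labels, mg, SPACING, gap_close_frames=1)
        assert out[1] == [(4, 8)]
        strict = tg.detect_bouton_contacts(labels, mg, SPACING, gap_close_frames=0)
        assert strict[1] == [(4, 5), (7, 8)]

    def test_no_bouton_labels_rejected(self):
        with pytest.raises(ValueError, match="bouton"):
            tg.detect_bouton_contacts(np.zeros(SHAPE, int),
                                      _microglia_run(set()), SPACING)


class TestEngulfment:
    def _session(self, transfer_frame=10, contact_onset=6, frac=0.3,
                 n_frames=16, delete_instead=False):
        """Noiseless mask session: contact, then partial transfer inward."""
        labels = _bouton_labels()
        presyn, mg = [], []
        r0 = 400.0
        for t in range(n_frames):
            m = make_sphere_mask(SHAPE, (5, 20, 10), 1200)
            p = np.zeros(SHAPE, bool)
            in_contact = contact_onset <= t
            if in_contact:
                m |= make_sphere_mask(SHAPE, (5, 20, 22), 900)  # process end
            if t < transfer_frame or delete_instead:
                if not (delete_instead and t >= transfer_frame):
                    p |= make_sphere_mask(SHAPE, (5, 20, 30), r0)
            else:
                p |= make_sphere_mask(SHAPE, (5, 20, 30),
                                      r0 * (1 - frac) ** (1 / 3))
                p |= make_sphere_mask(SHAPE, (5, 20, 20),
                                      r0 * frac ** (1 / 3))   # inside the end
            presyn.append(p)
            mg.append(m)
        return labels, np.stack(presyn), np.stack(mg)

    def test_scripted_latency_six_minutes(self):
        """Contact at frame 6, transfer at frame 10, 90 s frames -> 360 s."""
        labels, presyn, mg = self._session()
        contacts = tg.detect_bouton_contacts(labels, mg, SPACING)
        events = tg.detect_engulfment(presyn, mg, labels, contacts, SPACING, 90.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.internalization_frame == 10
        assert ev.latency_s == pytest.approx(360.0)
        assert ev.latency_s % 90.0 == 0.0

    def test_disappearance_without_internalization_is_not_engulfment(self):
        labels, presyn, mg = self._session(delete_instead=True)
        contacts = tg.detect_bouton_contacts(labels, mg, SPACING)
        events = tg.detect_engulfment(presyn, mg, labels, contacts, SPACING, 90.0)
        assert events == []

    def test_partial_transfer_fraction_and_residual(self):
        """30% scripted transfer recovered as engulfed_fraction ~ 0.3.

        Near-isotropic voxels here: with a 480 nm axial step, sub-µm
        spheres digitize to single-slice disks whose areas no longer
        scale like volumes.
        """
        iso = (130.0, 130.0, 130.0)
        shape = (24, 40, 40)
        frac = 0.3
        r0 = 500.0
        labels = np.where(make_sphere_mask(shape, (12, 20, 30), r0, iso), 1, 0)
        presyn, mg = [], []
        for t in range(16):
            m = make_sphere_mask(shape, (12, 20, 8), 1000, iso)
            if t >= 6:
                m |= make_sphere_mask(shape, (12, 20, 20), 900, iso)
            p = np.zeros(shape, bool)
            if t < 10:
                p |= make_sphere_mask(shape, (12, 20, 30), r0, iso)
            else:
                p |= make_sphere_mask(shape, (12, 20, 30),
                                      r0 * (1 - frac) ** (1 / 3), iso)
                p |= make_sphere_mask(shape, (12, 20, 20),
                                      r0 * frac ** (1 / 3), iso)
            presyn.append(p)
            mg.append(m)
        presyn, mg = np.stack(presyn), np.stack(mg)
        contacts = tg.detect_bouton_contacts(labels, mg, iso)
        events = tg.detect_engulfment(presyn, mg, labels, contacts, iso, 90.0)
        assert len(events) == 1
        assert events[0].engulfed_fraction == pytest.approx(0.3, abs=0.05)
        assert events[0].residual_at_site is True

    def test_missing_frame_interval_rejected(self):
        labels, presyn, mg = self._session()
        with pytest.raises(ValueError, match="frame_interval"):
            tg.detect_engulfment(presyn, mg, labels, {1: [(0, 5)]}, SPACING, 0)

    def test_rendered_session_recall_and_precision(self, trogo_session):
        """Full rendered pipeline recovers the scripted events 1:1."""
        grid, scene, vol, masks = trogo_session
        boutons = tg.segment_boutons(masks["presynaptic"][0],
                                     masks["microglia"][0],
                                     grid.voxel_spacing_nm)
        contacts = tg.detect_bouton_contacts(boutons, masks["microglia"],
                                             grid.voxel_spacing_nm)
        events = tg.detect_engulfment(
            masks["presynaptic"], masks["microglia"], boutons, contacts,
            grid.voxel_spacing_nm, grid.frame_interval_s,
        )
        gt = scene.events.of_type("engulfment")
        det = sorted((e.internalization_frame, e.contact_onset_frame)
                     for e in events)
        gts = sorted((int(r.offset_frame), int(r.onset_frame))
                     for r in gt.itertuples())
        assert det == gts
        assert len(events) >= 1

    def test_intensity_rescaling_invariance(self, trogo_session):
        """Doubling channel gain does not change detected events (threshold
        is relative to measured noise)."""
        from trogopy import preprocess as pp

        grid, scene, vol, masks = trogo_session
        events_ref = None
        for gain in (1.0, 2.0):
            scaled = {}
            for ch in ("microglia", "presynaptic"):
                frames = vol.channel(ch) * gain
                rule = pp.ThresholdRule(
                    pp.estimate_noise(frames[0],
                                      frames[0] <= 1.2 * np.median(frames[0]))
                )
                scaled[ch] = np.stack(
                    [pp.apply_threshold(frames[t], rule)
                     for t in range(grid.n_frames)]
                )
            boutons = tg.segment_boutons(scaled["presynaptic"][0],
                                         scaled["microglia"][0],
                                         grid.voxel_spacing_nm)
            contacts = tg.detect_bouton_contacts(boutons, scaled["microglia"],
                                                 grid.voxel_spacing_nm)
            events = sorted(
                e.internalization_frame
                for e in tg.detect_engulfment(
                    scaled["presynaptic"], scaled["microglia"], boutons,
                    contacts, grid.voxel_spacing_nm, grid.frame_interval_s)
            )
            if events_ref is None:
                events_ref = events
            else:
                assert events == events_ref


class TestInclusions:
    def test_clean_scene_zero(self):
        mg = make_sphere_mask(SHAPE, (5, 20, 20), 1500)
        assert tg.count_initial_inclusions(np.zeros(SHAPE, bool), mg,
                                           SPACING).n_inclusions == 0

    def test_three_scripted_inclusions_counted(self):
        mg = make_sphere_mask(SHAPE, (5, 20, 20), 2200)
        p = np.zeros(SHAPE, bool)
        for c in ((5, 20, 14), (5, 14, 20), (5, 26, 20)):
            p |= make_sphere_mask(SHAPE, c, 300)
        assert tg.count_initial_inclusions(p, mg, SPACING).n_inclusions == 3

    def test_boundary_touching_component_excluded(self):
        mg = make_sphere_mask(SHAPE, (5, 20, 20), 1500)
        p = make_sphere_mask(SHAPE, (5, 20, 31), 400)  # straddles the surface
        assert tg.count_initial_inclusions(p, mg, SPACING).n_inclusions == 0


class TestGroups:
    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"events_per_cell": [1.0, 2.0, 3.0],
                           "latency_s": [300.0, 360.0, 420.0],
                           "inclusions_per_cell": [2.0, 3.0, 2.0]})
        out = tg.compare_groups(df, df.copy())
        for ep in out:
            assert out[ep]["p"] == pytest.approx(1.0)

    def test_type_one_error_rate_calibrated(self):
        """Equal-rate cohorts rejected at alpha=0.05 in 2-9% of replicates."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = pd.DataFrame({"events_per_cell": rng.poisson(1.5, size=8) * 1.0})
            b = pd.DataFrame({"events_per_cell": rng.poisson(1.5, size=6) * 1.0})
            if a["events_per_cell"].var() == 0 or b["events_per_cell"].var() == 0:
                continue
            res = tg.compare_groups(a, b, endpoints=("events_per_cell",))
            rejections += res["events_per_cell"]["p"] < 0.05
        assert 0.02 * n_rep <= rejections <= 0.09 * n_rep

    def test_small_group_rejected(self):
        df = pd.DataFrame({"events_per_cell": [1.0]})
        with pytest.raises(ValueError, match="2 cells"):
            tg.compare_groups(df, df, endpoints=("events_per_cell",))
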