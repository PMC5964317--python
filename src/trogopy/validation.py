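"""Parameter-recovery experiments on synthetic sessions.

These drive the full pipeline — scene scripting, rendering, thresholding,
detection — against the generator's ground truth and report how well the
scripted study conditions (event rates, speeds) are recovered. They are
what the package's claims about detector calibration rest on.
"""

from __future__ import annotations

import math

import numpy as np

from . import preprocess as pp
from . import simulate as sim
from . import trogocytosis as tg
from .motility import detect_motility_events, summarize_motility
from .skeleton import skeletonize


def motility_recovery(n_replicates: int = 50, base_seed: int = 1,
                      n_frames: int = 4) -> dict:
    """Recover the scripted extension rate and speed over replicate cells.

    Each replicate is a noiseless-rendered session of ``n_frames`` frames
    one minute apart, analysed with skeletonize + detect_motility_events +
    summarize_motility. Returns across-cell means with standard errors,
    alongside the scripted ground truth.
    """
    grid = sim.GridSpec(shape=(24, 224, 224), n_frames=n_frames,
                        frame_interval_s=60.0)
    layout = sim.SceneLayout()
    acq = sim.AcquisitionModel(frame_interval_s=60.0).noiseless()
    rates, speeds_events, gt_rates = [], [], []
    for i in range(n_replicates):
        seed = base_seed * 100_000 + i
        params = sim.EventScriptParams(rng_seed=seed)
        scene = sim.build_scene(params, grid, layout, rng_seed=seed)
        vol = sim.render_timelapse(scene, acq, rng_seed=seed + 1)
        soma_vox = tuple(int(c / s) for c, s in
                         zip(scene.soma_center_nm, grid.voxel_spacing_nm))
        rule = pp.ThresholdRule(0.0)  # noiseless: any signal is structure
        skels = [
            skeletonize(pp.apply_threshold(vol.channel("microglia")[t], rule),
                        grid.voxel_spacing_nm, soma_vox)
            for t in range(grid.n_frames)
        ]
        events = []
        for t in range(grid.n_frames - 1):
            events += detect_motility_events(skels[t], skels[t + 1], 60.0,
                                             onset_frame=t)
        minutes = grid.n_frames - 1
        s = summarize_motility(events, minutes)
        rates.append(s["extension_rate_per_min"])
        speeds_events += [e.speed_um_min for e in events
                          if e.type == "extension"]
        gt_rates.append(len(scene.events.of_type("extension")) / minutes)
    rates = np.asarray(rates)
    return {
        "mean_extension_rate_per_min": float(rates.mean()),
        "se_extension_rate": float(rates.std(ddof=1) / math.sqrt(len(rates))),
        "scripted_extension_rate_per_min": 26.0,
        "scripted_realized_rate_per_min": float(np.mean(gt_rates)),
        "mean_extension_speed_um_min": float(np.mean(speeds_events)),
        "scripted_extension_speed_um_min": 1.9,
        "n_replicates": n_replicates,
        "n_extension_events": len(speeds_events),
    }


def trogocytosis_recovery(n_cells: int = 100, base_seed: int = 1) -> dict:
    """Recover the wild-type trogocytosis rate over replicate 3 h cells.

    Each cell is rendered with the default acquisition noise and analysed
    with segment_boutons + detect_bouton_contacts + detect_engulfment.
    Detected events are matched to the scripted ground truth (same
    internalization frame ±1) to measure recall and precision.
    """
    # 121 frames at 90 s = a full 3 h session (120 intervals)
    grid = sim.GridSpec(shape=(14, 160, 160), n_frames=121,
                        frame_interval_s=90.0)
    layout = sim.SceneLayout(n_motility_processes=0, n_axons=2)
    acq = sim.AcquisitionModel(frame_interval_s=90.0)
    per_cell, gt_per_cell = [], []
    n_matched = n_det = n_gt = 0
    for i in range(n_cells):
        seed = base_seed * 100_000 + i
        scene = sim.build_scene(sim.EventScriptParams(rng_seed=seed), grid,
                                layout, rng_seed=seed)
        vol = sim.render_timelapse(scene, acq, rng_seed=seed + 1)
        masks = {}
        for ch in ("microglia", "presynaptic"):
            fr = vol.channel(ch)[0]
            rule = pp.ThresholdRule(
                pp.estimate_noise(fr, fr <= 1.2 * np.median(fr))
            )
            masks[ch] = np.stack(
                [pp.apply_threshold(vol.channel(ch)[t], rule)
                 for t in range(grid.n_frames)]
            )
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
        det_frames = sorted(e.internalization_frame for e in events)
        gt_frames = sorted(int(f) for f in gt["offset_frame"]) if len(gt) else []
        used = set()
        matched = 0
        for f in det_frames:
            for k, g in enumerate(gt_frames):
                if k not in used and abs(f - g) <= 1:
                    used.add(k)
                    matched += 1
                    break
        n_matched += matched
        n_det += len(det_frames)
        n_gt += len(gt_frames)
        per_cell.append(len(det_frames))
        gt_per_cell.append(len(gt_frames))
    per_cell = np.asarray(per_cell, dtype=float)
    return {
        "mean_events_per_cell_3h": float(per_cell.mean()),
        "se_events_per_cell": float(per_cell.std(ddof=1) / math.sqrt(len(per_cell))),
        "scripted_rate_per_cell_3h": 1.5,
        "scripted_realized_per_cell": float(np.mean(gt_per_cell)),
        "recall": float(n_matched / n_gt) if n_gt else float("nan"),
        "precision": float(n_matched / n_det) if n_det else float("nan"),
        "n_cells": n_cells,
        "n_events_detected": int(n_det),
        "n_events_scripted": int(n_gt),
    }
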