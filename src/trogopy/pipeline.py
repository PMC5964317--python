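"""Reproducible simulate -> preprocess -> analyze -> report runs.

A single JSON configuration with per-stage sections drives every stage;
unknown keys are rejected, every stochastic stage requires a seed, and
each run appends a line (config hash, seed) to a structured run log so
any output can be reproduced. Stage outputs are CSV/TIFF files in the
output directory, which also receives a copy of the resolved config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage

from . import contacts as contacts_mod
from . import inclusions as inclusions_mod
from . import motility as motility_mod
from . import preprocess, simulate, spines as spines_mod, trogocytosis as trogo_mod
from .io import RunLog, read_labels, read_stack, write_stack
from .skeleton import skeletonize

STAGES = ("simulate", "preprocess", "motility", "contacts", "trogo", "spines",
          "inclusions", "report", "all")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    rng_seed: int
    grid_shape: tuple[int, int, int] = (16, 192, 192)
    voxel_spacing_nm: tuple[float, float, float] = (480.0, 130.0, 130.0)
    n_frames: int = 8
    frame_interval_s: float = 90.0
    n_motility_processes: int = 0
    n_spines: int = 0
    n_axons: int = 0
    render_seed: int = 1
    noiseless: bool = False
    params: dict = Field(default_factory=dict)
    layout: dict = Field(default_factory=dict)


class PreprocessConfig(_Strict):
    threshold_multiplier: float = 1.4
    noise_statistic: str = "mean"
    drift_reference_channel: str = "microglia"
    correct_drift: bool = False


class MotilityConfig(_Strict):
    delta_s: float = 60.0
    min_displacement_um: float = 0.26
    match_radius_um: float = 3.5


class ContactConfig(_Strict):
    distance_nm: float = 260.0


class TrogoConfig(_Strict):
    contact_distance_nm: float = 260.0
    min_engulfed_volume_um3: float = 0.005
    residual_min_fraction: float = 0.05
    gap_close_frames: int = 1


class SpinesConfig(_Strict):
    max_lag: int = 5
    n_boot: int = 1000
    rng_seed: int = 0
    min_shf_length_um: float = 0.4
    neighbor_radius_um: float = 4.0


class InclusionsConfig(_Strict):
    labels_path: str | None = None
    microglia_id: int = 1


class RunConfig(_Strict):
    """Validated per-stage configuration for a pipeline run."""

    out_dir: str
    simulate: SimulateConfig
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    motility: MotilityConfig = Field(default_factory=MotilityConfig)
    contact: ContactConfig = Field(default_factory=ContactConfig)
    trogo: TrogoConfig = Field(default_factory=TrogoConfig)
    spines: SpinesConfig = Field(default_factory=SpinesConfig)
    inclusions: InclusionsConfig = Field(default_factory=InclusionsConfig)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


class DependencyError(RuntimeError):
    """A stage's upstream output is missing."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"missing upstream output {path.name} (run '{stage}' first)")
    return path


def _auto_noise(frame: np.ndarray, statistic: str) -> float:
    """Background level of a frame: mean (or median) of the sub-1.2x-median
    band, i.e. intensities measured outside any labelled structure."""
    med = float(np.median(frame))
    background = frame <= 1.2 * med if med > 0 else frame <= np.percentile(frame, 60)
    return preprocess.estimate_noise(frame, background, statistic=statistic)


def run(subcommand: str, config: RunConfig) -> dict:
    """Execute one pipeline stage (or ``all``); returns a result summary."""
    if subcommand not in STAGES:
        raise ValueError(f"unknown subcommand {subcommand!r}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.json", "w") as fh:
        fh.write(config.model_dump_json(indent=2))
    log = RunLog(out / "run_log.jsonl")
    results: dict = {}
    stages = (
        ["simulate", "preprocess", "motility", "contacts", "trogo", "spines",
         "inclusions", "report"]
        if subcommand == "all" else [subcommand]
    )
    for stage in stages:
        fn = _STAGE_FUNCS[stage]
        results[stage] = fn(config, out, log)
    return results


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, out: Path, log: RunLog) -> dict:
    sc = config.simulate
    grid = simulate.GridSpec(
        shape=sc.grid_shape, voxel_spacing_nm=sc.voxel_spacing_nm,
        n_frames=sc.n_frames, frame_interval_s=sc.frame_interval_s,
    )
    params = simulate.EventScriptParams(rng_seed=sc.rng_seed, **sc.params)
    layout = simulate.SceneLayout(
        n_motility_processes=sc.n_motility_processes, n_spines=sc.n_spines,
        n_axons=sc.n_axons, **sc.layout,
    )
    scene = simulate.build_scene(params, grid, layout, rng_seed=sc.rng_seed)
    acq = simulate.AcquisitionModel(
        voxel_spacing_nm=sc.voxel_spacing_nm, frame_interval_s=sc.frame_interval_s,
    )
    if sc.noiseless:
        acq = acq.noiseless()
    vol = simulate.render_timelapse(scene, acq, rng_seed=sc.render_seed)
    write_stack(vol, out / "timelapse.tif")
    simulate.write_ground_truth(scene.events, out / "ground_truth_events.csv")
    meta = {
        "soma_center_nm": np.asarray(scene.soma_center_nm).tolist(),
        "channel_names": list(scene.channel_names),
        "bouton_centers_nm": {k: v.tolist() for k, v in scene.bouton_centers_nm.items()},
        "dendrite_axis_nm": (
            [p.tolist() for p in scene.dendrite_axis_nm]
            if scene.dendrite_axis_nm else None
        ),
        "spines": [
            {
                "base_point_nm": s.base_point_nm.tolist(),
                "direction": s.direction.tolist(),
                "neck_length_nm": s.neck_length_nm,
                "head_radius_nm": s.head_radius_nm,
            }
            for s in scene.spines
        ],
    }
    with open(out / "scene.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    log.record("simulate", seed=sc.rng_seed, config=config.model_dump(),
               n_events=len(scene.events))
    return {"n_events": len(scene.events)}


def _load_session(config: RunConfig, out: Path):
    vol = read_stack(_require(out / "timelapse.tif", "simulate"))
    with open(_require(out / "scene.json", "simulate")) as fh:
        meta = json.load(fh)
    return vol, meta


def _stage_preprocess(config: RunConfig, out: Path, log: RunLog) -> dict:
    vol, _ = _load_session(config, out)
    pc = config.preprocess
    if pc.correct_drift:
        vol, trace = preprocess.correct_drift(vol, pc.drift_reference_channel)
        np.savetxt(out / "drift_trace.csv", trace.shifts, fmt="%d", delimiter=",",
                   header="dz,dy,dx", comments="")
    cutoffs = {}
    masks = np.zeros(vol.data.shape, dtype=bool)
    for ci, ch in enumerate(vol.channel_names):
        noise = _auto_noise(vol.data[0, ci], pc.noise_statistic)
        rule = preprocess.ThresholdRule(noise, pc.threshold_multiplier)
        cutoffs[ch] = rule.cutoff
        for t in range(vol.n_frames):
            masks[t, ci] = preprocess.apply_threshold(vol.data[t, ci], rule)
    np.savez_compressed(out / "masks.npz", masks=masks,
                        channel_names=np.array(vol.channel_names))
    with open(out / "cutoffs.json", "w") as fh:
        json.dump(cutoffs, fh, indent=2)
    log.record("preprocess", config=config.model_dump(), cutoffs=cutoffs)
    return {"cutoffs": cutoffs}


def _load_masks(out: Path) -> tuple[np.ndarray, list[str]]:
    data = np.load(_require(out / "masks.npz", "preprocess"), allow_pickle=False)
    return data["masks"], [str(c) for c in data["channel_names"]]


def _stage_motility(config: RunConfig, out: Path, log: RunLog) -> dict:
    vol, meta = _load_session(config, out)
    masks, channels = _load_masks(out)
    mg = masks[:, channels.index("microglia")]
    soma_vox = tuple(
        int(c / s) for c, s in zip(meta["soma_center_nm"], vol.voxel_spacing_nm)
    )
    mc = config.motility
    step = max(1, round(mc.delta_s / vol.frame_interval_s))
    skels = [skeletonize(mg[t], vol.voxel_spacing_nm, soma_vox)
             for t in range(vol.n_frames)]
    events = []
    for t in range(0, vol.n_frames - step, step):
        events.extend(
            motility_mod.detect_motility_events(
                skels[t], skels[t + step], interval_s=step * vol.frame_interval_s,
                min_displacement_um=mc.min_displacement_um,
                match_radius_um=mc.match_radius_um, onset_frame=t,
            )
        )
    minutes = (vol.n_frames - 1) * vol.frame_interval_s / 60.0
    summary = motility_mod.summarize_motility(events, minutes)
    pd.DataFrame(
        [e.__dict__ | {"speed_um_min": e.speed_um_min} for e in events],
        columns=["type", "tip_id", "displacement_um", "interval_s",
                 "onset_frame", "speed_um_min"],
    ).to_csv(out / "motility_events.csv", index=False)
    pd.DataFrame([summary]).to_csv(out / "motility_summary.csv", index=False)
    log.record("motility", config=config.model_dump())
    return summary


def _stage_contacts(config: RunConfig, out: Path, log: RunLog) -> dict:
    vol, meta = _load_session(config, out)
    masks, channels = _load_masks(out)
    if not meta["spines"]:
        raise DependencyError("scene has no spines; nothing to classify")
    mg = masks[0, channels.index("microglia")]
    spine_masks = spines_mod.extract_spine_masks(
        masks[:, channels.index("neuron")],
        tuple(np.asarray(p) for p in meta["dendrite_axis_nm"]),
        [np.asarray(s["base_point_nm"]) for s in meta["spines"]],
        vol.voxel_spacing_nm,
    )
    records = []
    for j, sm in spine_masks.items():
        if not sm[0].any():
            continue
        head = spines_mod._head_region(sm[0], vol.voxel_spacing_nm)
        frac = contacts_mod.coverage_fraction(
            head, mg, vol.voxel_spacing_nm, config.contact.distance_nm
        )
        records.append(
            contacts_mod.ContactRecord(
                spine_id=j, coverage_fraction=frac,
                contact_class=contacts_mod.classify_contact(frac),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in records],
                      columns=["spine_id", "coverage_fraction", "contact_class",
                               "neck_intact", "marker_apposed"])
    df.to_csv(out / "contact_records.csv", index=False)
    summary = contacts_mod.summarize_contacts(records, max(len(records), 1))
    log.record("contacts", config=config.model_dump())
    return summary


def _stage_trogo(config: RunConfig, out: Path, log: RunLog) -> dict:
    vol, _ = _load_session(config, out)
    masks, channels = _load_masks(out)
    mg = masks[:, channels.index("microglia")]
    pre = masks[:, channels.index("presynaptic")]
    tc = config.trogo
    boutons = trogo_mod.segment_boutons(pre[0], mg[0], vol.voxel_spacing_nm)
    contacts = trogo_mod.detect_bouton_contacts(
        boutons, mg, vol.voxel_spacing_nm, tc.contact_distance_nm,
        tc.gap_close_frames,
    )
    events = trogo_mod.detect_engulfment(
        pre, mg, boutons, contacts, vol.voxel_spacing_nm, vol.frame_interval_s,
        min_engulfed_volume_um3=tc.min_engulfed_volume_um3,
        residual_min_fraction=tc.residual_min_fraction,
    )
    inc = trogo_mod.count_initial_inclusions(pre[0], mg[0], vol.voxel_spacing_nm)
    columns = ["bouton_id", "contact_onset_frame", "internalization_frame",
               "latency_s", "engulfed_fraction", "residual_at_site"]
    pd.DataFrame(
        [
            {
                "bouton_id": e.bouton_id,
                "contact_onset_frame": e.contact_onset_frame,
                "internalization_frame": e.internalization_frame,
                "latency_s": e.latency_s,
                "engulfed_fraction": e.engulfed_fraction,
                "residual_at_site": e.residual_at_site,
            }
            for e in events
        ],
        columns=columns,
    ).to_csv(out / "engulfment_events.csv", index=False)
    summary = {"n_events": len(events), "n_initial_inclusions": inc.n_inclusions,
               "mean_latency_s": (
                   float(np.mean([e.latency_s for e in events])) if events else None)}
    log.record("trogo", config=config.model_dump(), **summary)
    return summary


def _stage_spines(config: RunConfig, out: Path, log: RunLog) -> dict:
    vol, meta = _load_session(config, out)
    masks, channels = _load_masks(out)
    if not meta["spines"]:
        raise DependencyError("scene has no spines; nothing to analyze")
    with open(_require(out / "cutoffs.json", "preprocess")) as fh:
        cutoffs = json.load(fh)
    spine_masks = spines_mod.extract_spine_masks(
        masks[:, channels.index("neuron")],
        tuple(np.asarray(p) for p in meta["dendrite_axis_nm"]),
        [np.asarray(s["base_point_nm"]) for s in meta["spines"]],
        vol.voxel_spacing_nm,
    )
    neuron_ci = channels.index("neuron")
    mg_ci = channels.index("microglia")
    dend = masks[0, neuron_ci]
    tracks = []
    for j, sm in spine_masks.items():
        if not sm.any():
            continue
        try:
            tracks.append(
                spines_mod.spine_metrics(
                    sm, dend, vol.data[:, neuron_ci], vol.data[:, mg_ci],
                    cutoffs["microglia"], vol.voxel_spacing_nm, spine_id=j,
                )
            )
        except ValueError:
            continue
    rows = []
    for tr in tracks:
        for i, f in enumerate(tr.frames):
            rows.append(
                {"spine_id": tr.spine_id, "frame": int(f),
                 "length_um": tr.length_um[i],
                 "head_intensity": tr.head_intensity[i],
                 "contact_extent": tr.contact_extent[i]}
            )
    pd.DataFrame(rows, columns=["spine_id", "frame", "length_um",
                                "head_intensity", "contact_extent"]
                 ).to_csv(out / "spine_tracks.csv", index=False)
    fates = spines_mod.classify_spine_fates(tracks, vol.n_frames)
    fates.to_csv(out / "spine_fates.csv", index=False)
    durs = spines_mod.contact_durations(tracks, vol.frame_interval_s)
    durs.to_csv(out / "contact_durations.csv", index=False)
    log.record("spines", config=config.model_dump(), n_tracks=len(tracks))
    return {"n_tracks": len(tracks),
            "mean_contact_min": (
                float(durs["duration_min"].mean()) if len(durs) else None)}


def _stage_inclusions(config: RunConfig, out: Path, log: RunLog) -> dict:
    ic = config.inclusions
    if ic.labels_path is None:
        return {"skipped": "no label volume configured"}
    labels = read_labels(ic.labels_path)
    records = inclusions_mod.enumerate_inclusions(labels, ic.microglia_id)
    inclusions_mod.records_to_frame(records).to_csv(
        out / "inclusion_records.csv", index=False
    )
    if records:
        dist = inclusions_mod.size_distribution(records)
        summary = {"n": dist["n"], "mean_diameter_nm": dist["mean_diameter_nm"]}
    else:
        summary = {"n": 0, "mean_diameter_nm": None}
    log.record("inclusions", config=config.model_dump(), **summary)
    return summary


def _stage_report(config: RunConfig, out: Path, log: RunLog) -> dict:
    """Aggregate the stage CSVs into one headline-quantity summary table."""

    def _read(path: Path) -> pd.DataFrame:
        if not path.exists():
            return pd.DataFrame()
        try:
            return pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return pd.DataFrame()

    rows: list[dict] = []
    mot = _read(out / "motility_summary.csv")
    if len(mot):
        rows.append({"quantity": "extension_rate_per_min",
                     "value": float(mot["extension_rate_per_min"].iloc[0])})
        rows.append({"quantity": "retraction_rate_per_min",
                     "value": float(mot["retraction_rate_per_min"].iloc[0])})
        rows.append({"quantity": "mean_extension_speed_um_min",
                     "value": float(mot["mean_extension_speed_um_min"].iloc[0])})
    eng = _read(out / "engulfment_events.csv")
    rows.append({"quantity": "trogocytosis_events", "value": float(len(eng))})
    if len(eng):
        rows.append({"quantity": "mean_latency_min",
                     "value": float(eng["latency_s"].mean() / 60.0)})
    contacts = _read(out / "contact_records.csv")
    if len(contacts):
        for cls in ("apposition", "encapsulation"):
            rows.append({
                "quantity": f"{cls}_percent_of_spines",
                "value": round(
                    100.0 * (contacts["contact_class"] == cls).sum()
                    / len(contacts), 1),
            })
    durs = _read(out / "contact_durations.csv")
    if len(durs):
        rows.append({"quantity": "mean_contact_duration_min",
                     "value": float(durs["duration_min"].mean())})
    report = pd.DataFrame(rows, columns=["quantity", "value"])
    report.to_csv(out / "report_summary.csv", index=False)
    log.record("report", config=config.model_dump())
    return {"quantities_reported": len(rows)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "motility": _stage_motility,
    "contacts": _stage_contacts,
    "trogo": _stage_trogo,
    "spines": _stage_spines,
    "inclusions": _stage_inclusions,
    "report": _stage_report,
}
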