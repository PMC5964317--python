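"""Detection of presynaptic-material engulfment (trogocytosis) events.

A trogocytosis event is a presynaptic-label component that newly appears
fully inside the microglia (mask eroded by one voxel), is large enough
not to be single-voxel noise, and is spatially continuous with a bouton
the microglia was contacting at the previous frame. Latency is the
contact time elapsed before any material is seen internalized.
Pre-existing internal material (origin unknowable) is counted separately
as inclusions at the session start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .motility import welch_t

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class EngulfmentEvent:
    bouton_id: int
    contact_onset_frame: int
    internalization_frame: int
    latency_s: float
    engulfed_fraction: float
    residual_at_site: bool
    trafficking_trace: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.internalization_frame < self.contact_onset_frame:
            raise ValueError("internalization precedes contact onset")


@dataclass
class InclusionCount:
    cell_id: int | str
    n_inclusions: int

    def __post_init__(self) -> None:
        if self.n_inclusions < 0:
            raise ValueError("inclusion count must be nonnegative")


def segment_boutons(presyn_mask0: np.ndarray, microglia_mask0: np.ndarray,
                    spacing_nm: tuple[float, float, float],
                    min_volume_um3: float = 0.02) -> np.ndarray:
    """Label candidate boutons at the session start.

    Boutons are 26-connected components of the presynaptic mask that are
    not already fully inside the microglia (those are inclusions) and
    exceed a minimum volume (which also drops thin axon-shaft remnants).
    """
    labels, n = ndimage.label(np.asarray(presyn_mask0, bool), structure=_STRUCT26)
    if n == 0:
        raise ValueError("no presynaptic structures found: no bouton labels")
    voxel_um3 = float(np.prod(np.asarray(spacing_nm) / 1000.0))
    inner = ndimage.binary_erosion(np.asarray(microglia_mask0, bool),
                                   structure=_STRUCT6, border_value=0)
    out = np.zeros_like(labels)
    next_id = 1
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() * voxel_um3 < min_volume_um3:
            continue
        if np.all(inner[comp]):
            continue  # pre-existing inclusion, not a bouton
        out[comp] = next_id
        next_id += 1
    return out


def detect_bouton_contacts(bouton_labels: np.ndarray,
                           microglia_masks: np.ndarray,
                           spacing_nm: tuple[float, float, float],
                           contact_distance_nm: float = 260.0,
                           gap_close_frames: int = 1
                           ) -> dict[int, list[tuple[int, int]]]:
    """Per-bouton maximal runs of frames in contact with the microglia.

    A bouton is in contact at frame t when any of its surface voxels lies
    within ``contact_distance_nm`` of the microglia mask. Single-frame
    dropouts up to ``gap_close_frames`` are bridged.
    """
    bouton_labels = np.asarray(bouton_labels)
    ids = sorted(int(b) for b in (set(np.unique(bouton_labels)) - {0}))
    if not ids:
        raise ValueError("no bouton labels provided")
    n_frames = microglia_masks.shape[0]
    spacing = np.asarray(spacing_nm, dtype=float)
    pad = np.ceil(contact_distance_nm / spacing).astype(int) + 1
    shape = np.asarray(bouton_labels.shape)
    # per-bouton padded bounding boxes: the distance transform only needs
    # to see microglia within contact range of the bouton
    boxes = {}
    for b in ids:
        coords = np.argwhere(bouton_labels == b)
        lo = np.maximum(coords.min(axis=0) - pad, 0)
        hi = np.minimum(coords.max(axis=0) + pad + 1, shape)
        sl = tuple(slice(int(a), int(z)) for a, z in zip(lo, hi))
        boxes[b] = (sl, (bouton_labels[sl] == b))
    in_contact = {b: np.zeros(n_frames, dtype=bool) for b in ids}
    for t in range(n_frames):
        mg = np.asarray(microglia_masks[t], bool)
        for b in ids:
            sl, bmask = boxes[b]
            sub = mg[sl]
            if not sub.any():
                continue
            dist = ndimage.distance_transform_edt(~sub, sampling=spacing_nm)
            in_contact[b][t] = bool((dist[bmask] <= contact_distance_nm).any())
    out: dict[int, list[tuple[int, int]]] = {}
    for b in ids:
        flags = in_contact[b]
        # close short gaps
        runs = _runs(flags)
        merged: list[list[int]] = []
        for a, z in runs:
            if merged and a - merged[-1][1] - 1 <= gap_close_frames:
                merged[-1][1] = z
            else:
                merged.append([a, z])
        out[b] = [tuple(r) for r in merged]
    return out


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def detect_engulfment(presyn_masks: np.ndarray, microglia_masks: np.ndarray,
                      bouton_labels: np.ndarray,
                      contacts: dict[int, list[tuple[int, int]]],
                      spacing_nm: tuple[float, float, float],
                      frame_interval_s: float,
                      min_engulfed_volume_um3: float = 0.005,
                      assoc_distance_um: float = 3.0,
                      residual_min_fraction: float = 0.05,
                      new_overlap_max: float = 0.3) -> list[EngulfmentEvent]:
    """Scan a session for newly internalized presynaptic components.

    For each frame t >= 1, presynaptic components whose voxels all lie in
    the one-voxel-eroded microglia mask, exceed the minimum volume, did
    not overlap presynaptic signal at t-1 (they are new), and sit within
    ``assoc_distance_um`` of a bouton in contact at t-1, are emitted as
    engulfment events. One event per (bouton, contact interval).
    """
    if frame_interval_s is None or frame_interval_s <= 0:
        raise ValueError("frame_interval_s missing or nonpositive")
    spacing_um = np.asarray(spacing_nm, dtype=float) / 1000.0
    voxel_um3 = float(np.prod(spacing_um))
    n_frames = presyn_masks.shape[0]
    bouton_labels = np.asarray(bouton_labels)
    centroids = {
        b: np.asarray(ndimage.center_of_mass(bouton_labels == b))
        for b in sorted(set(np.unique(bouton_labels)) - {0})
    }
    onset_volumes: dict[tuple[int, int], float] = {}
    events: list[EngulfmentEvent] = []
    claimed: set[tuple[int, int]] = set()
    # engulfed material appears at a location that was empty before the
    # session; components sitting on the static frame-0 presynaptic
    # footprint are structure flicker, not internalized material
    static_footprint = ndimage.binary_dilation(
        np.asarray(presyn_masks[0], bool), structure=_STRUCT26
    )

    for t in range(1, n_frames):
        inner = ndimage.binary_erosion(np.asarray(microglia_masks[t], bool),
                                       structure=_STRUCT6, border_value=0)
        labels, n = ndimage.label(np.asarray(presyn_masks[t], bool),
                                  structure=_STRUCT26)
        if n == 0:
            continue
        prev = np.asarray(presyn_masks[t - 1], bool)
        sizes = np.bincount(labels.ravel())
        objects = ndimage.find_objects(labels)
        for lab in range(1, n + 1):
            size = int(sizes[lab])
            if size * voxel_um3 < min_engulfed_volume_um3:
                continue
            sl = objects[lab - 1]
            comp_local = labels[sl] == lab
            if not np.all(inner[sl][comp_local]):
                continue
            if prev[sl][comp_local].mean() > new_overlap_max:
                continue  # already present: inclusion or trafficked material
            if static_footprint[sl][comp_local].mean() > 0.5:
                continue
            offset = np.array([s.start for s in sl], dtype=float)
            centroid = np.asarray(ndimage.center_of_mass(comp_local)) + offset
            best, best_d = None, np.inf
            for b, runs in contacts.items():
                active = [r for r in runs if r[0] <= t - 1 <= r[1] + 1]
                if not active:
                    continue
                d = float(
                    np.linalg.norm((centroid - centroids[b]) * spacing_um)
                )
                if d < best_d:
                    best, best_d, run = b, d, active[0]
            if best is None or best_d > assoc_distance_um:
                continue
            key = (best, run[0])
            if key in claimed:
                continue
            claimed.add(key)
            if key not in onset_volumes:
                bmask = (bouton_labels == best) & np.asarray(
                    presyn_masks[run[0]], bool
                )
                onset_volumes[key] = max(int(bmask.sum()), 1)
            frac = min(1.0, size / onset_volumes[key])
            res_now = int(
                ((bouton_labels == best) & np.asarray(presyn_masks[t], bool)).sum()
            )
            events.append(
                EngulfmentEvent(
                    bouton_id=int(best),
                    contact_onset_frame=int(run[0]),
                    internalization_frame=int(t),
                    latency_s=(t - run[0]) * frame_interval_s,
                    engulfed_fraction=float(frac),
                    residual_at_site=bool(
                        res_now >= residual_min_fraction * onset_volumes[key]
                    ),
                    trafficking_trace=[tuple(centroid * spacing_um * 1000.0)],
                )
            )
    return events


def count_initial_inclusions(presyn_mask0: np.ndarray,
                             microglia_mask0: np.ndarray,
                             spacing_nm: tuple[float, float, float],
                             min_inclusion_volume_um3: float = 0.005,
                             cell_id: int | str = 0) -> InclusionCount:
    """Presynaptic components fully inside the microglia at frame 0."""
    voxel_um3 = float(np.prod(np.asarray(spacing_nm) / 1000.0))
    inner = ndimage.binary_erosion(np.asarray(microglia_mask0, bool),
                                   structure=_STRUCT6, border_value=0)
    labels, n = ndimage.label(np.asarray(presyn_mask0, bool), structure=_STRUCT26)
    count = 0
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() * voxel_um3 < min_inclusion_volume_um3:
            continue
        if np.all(inner[comp]):
            count += 1
    return InclusionCount(cell_id=cell_id, n_inclusions=count)


def compare_groups(group_a: pd.DataFrame, group_b: pd.DataFrame,
                   endpoints: tuple[str, ...] = (
                       "events_per_cell", "latency_s", "inclusions_per_cell")
                   ) -> dict[str, dict]:
    """Welch two-sided t statistics per endpoint for two cell cohorts.

    Each DataFrame holds one row per cell with the endpoint columns.
    """
    out = {}
    for ep in endpoints:
        a = group_a[ep].dropna()
        b = group_b[ep].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"endpoint {ep}: need >= 2 cells per group")
        out[ep] = welch_t(a, b)
    return out
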