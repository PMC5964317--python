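"""Microglia-spine contact classification in single volumes.

A contact is graded by the fraction of the spine head's surface covered
by microglia: 20-50% coverage is an apposition, above 70% an
encapsulation; the (50%, 70%] gap is reported explicitly as
"intermediate" and below 20% as "none". Neck integrity and apposition of
a phagosome-marker channel are checked alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

APPOSITION_RANGE = (0.20, 0.50)
ENCAPSULATION_MIN = 0.70


@dataclass
class ContactRecord:
    spine_id: int | str
    coverage_fraction: float
    contact_class: str
    neck_intact: bool | None = None
    marker_apposed: bool | None = None


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of voxels with at least one 6-neighbour outside."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def coverage_fraction(head_mask: np.ndarray, microglia_mask: np.ndarray,
                      spacing_nm: tuple[float, float, float],
                      contact_distance_nm: float = 260.0) -> float:
    """Fraction of head-surface voxels within reach of the microglia.

    Distance is anisotropic Euclidean (via a distance transform sampled at
    the surface voxels). Monotone nondecreasing under dilation of the
    microglia mask.
    """
    head_mask = np.asarray(head_mask, dtype=bool)
    microglia_mask = np.asarray(microglia_mask, dtype=bool)
    if head_mask.shape != microglia_mask.shape:
        raise ValueError("masks are not aligned")
    if not head_mask.any():
        raise ValueError("empty head mask")
    surf = surface_voxels(head_mask)
    if not microglia_mask.any():
        return 0.0
    dist = ndimage.distance_transform_edt(~microglia_mask, sampling=spacing_nm)
    covered = dist[surf] <= contact_distance_nm
    return float(covered.mean())


def classify_contact(fraction: float) -> str:
    """Map a coverage fraction to its contact class."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"coverage fraction {fraction} outside [0, 1]")
    if fraction > ENCAPSULATION_MIN:
        return "encapsulation"
    if fraction > APPOSITION_RANGE[1]:
        return "intermediate"
    if fraction >= APPOSITION_RANGE[0]:
        return "apposition"
    return "none"


def neck_intact(spine_mask: np.ndarray, dendrite_mask: np.ndarray) -> bool:
    """True iff the spine remains 26-connected to its dendrite."""
    spine_mask = np.asarray(spine_mask, dtype=bool)
    dendrite_mask = np.asarray(dendrite_mask, dtype=bool)
    if not spine_mask.any():
        raise ValueError("empty spine mask")
    both = spine_mask | dendrite_mask
    labels, _ = ndimage.label(both, structure=_STRUCT26)
    spine_labels = set(np.unique(labels[spine_mask])) - {0}
    dendrite_labels = set(np.unique(labels[dendrite_mask])) - {0}
    return bool(spine_labels & dendrite_labels)


def marker_apposed(head_mask: np.ndarray, marker_mask: np.ndarray,
                   spacing_nm: tuple[float, float, float],
                   distance_nm: float = 500.0) -> bool:
    """True iff any marker voxel lies within reach of the head surface."""
    marker_mask = np.asarray(marker_mask, dtype=bool)
    if not marker_mask.any():
        return False
    surf = surface_voxels(np.asarray(head_mask, dtype=bool))
    if not surf.any():
        return False
    dist = ndimage.distance_transform_edt(~marker_mask, sampling=spacing_nm)
    return bool((dist[surf] <= distance_nm).any())


def per_cell_marker_intensity(cell_labels: np.ndarray, marker_volume: np.ndarray,
                              cell_ids=None):
    """Mean marker intensity over each labelled cell's voxels."""
    cell_labels = np.asarray(cell_labels)
    marker_volume = np.asarray(marker_volume)
    if cell_labels.shape != marker_volume.shape:
        raise ValueError("label and marker volumes are not aligned")
    present = set(np.unique(cell_labels)) - {0}
    if cell_ids is None:
        cell_ids = sorted(present)
    out = {}
    for cid in cell_ids:
        if cid not in present:
            raise ValueError(f"label {cid} absent from the volume")
        out[cid] = float(marker_volume[cell_labels == cid].mean())
    return out


def summarize_contacts(records: list[ContactRecord], n_spines_total: int) -> dict:
    """Percentage of spines per contact class, to one decimal."""
    if n_spines_total <= 0:
        raise ValueError("total spine count must be positive")
    if n_spines_total < len(records):
        raise ValueError("more contact records than total spines")
    classes = ("apposition", "encapsulation", "intermediate", "none")
    counts = {c: sum(1 for r in records if r.contact_class == c) for c in classes}
    return {
        f"{c}_percent": round(100.0 * counts[c] / n_spines_total, 1) for c in classes
    } | {f"{c}_count": counts[c] for c in classes}
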