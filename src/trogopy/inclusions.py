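"""Morphometry of microglial inclusions on 3D label volumes.

Works on EM-style segmentation labels: foreign-material (bouton, axon, or
microglial self) components inside a microglia are enumerated, measured
(anisotropic voxel volume, volume-equivalent spherical diameter), and
classified as complete (fully enclosed) or partial (still continuous
with parent material outside the cell, i.e. "pinched").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

_FOREIGN_SOURCES = {"bouton": "bouton", "axon": "axon", "spine": "undetermined",
                    "dendrite": "undetermined", "inclusion": "undetermined",
                    "microglia": "self"}


@dataclass
class InclusionRecord:
    inclusion_id: int
    volume_um3: float
    equivalent_diameter_nm: float
    completeness: str            # "complete" | "partial"
    source: str                  # "bouton" | "axon" | "self" | "undetermined"
    voxel_count: int = 0
    max_feret_nm: float | None = None


def equivalent_diameter(volume_um3: float) -> float:
    """Volume-equivalent sphere diameter in nm for a volume in µm³."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return 1000.0 * (6.0 * volume_um3 / math.pi) ** (1.0 / 3.0)


def _max_feret_nm(coords: np.ndarray, spacing_nm) -> float:
    pts = coords * np.asarray(spacing_nm)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 400:  # caliper on the bounding subset is enough at this scale
        sel = np.unique(np.concatenate([
            pts[np.argsort(pts[:, ax])[[0, -1]]] for ax in range(3)
        ]), axis=0)
        hull = pts if len(sel) < 4 else pts[np.random.default_rng(0).choice(
            len(pts), 400, replace=False)]
        pts = np.concatenate([hull, sel])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    return float(d.max())


def enumerate_inclusions(labels: LabelVolume, microglia_id: int,
                         compute_feret: bool = False,
                         closing_iterations: int = 2) -> list[InclusionRecord]:
    """Components of non-microglia material inside one microglia.

    26-connected components of foreign-class voxels that intersect the
    microglia interior; each is tagged with its source class from the
    label table and classified complete/partial by continuity with
    same-label material outside the cell.
    """
    grid = labels.data
    if grid.ndim != 3:
        raise ValueError("inclusion morphometry expects a (z, y, x) label volume")
    if microglia_id not in labels.label_table:
        raise ValueError(f"microglia label {microglia_id} absent from label table")
    if labels.label_table[microglia_id] != "microglia":
        raise ValueError(f"label {microglia_id} is not a microglia")
    cell = grid == microglia_id
    if not cell.any():
        raise ValueError(f"microglia label {microglia_id} absent from the volume")
    # the microglia "interior" is the filled volume of its main body:
    # anything sitting within it — including detached fragments of the
    # same microglia label (self-engulfment) — is inside the cell
    cell_comps, n_cell = ndimage.label(cell, structure=_STRUCT26)
    sizes = ndimage.sum_labels(cell, cell_comps, index=range(1, n_cell + 1))
    main = cell_comps == (1 + int(np.argmax(sizes)))
    # a pinched ("partial") inclusion keeps a thin channel to the outside,
    # so the raw cavity is not topologically closed; a small morphological
    # closing seals channels narrower than ~closing_iterations voxels
    # before the cavities are filled
    struct6 = ndimage.generate_binary_structure(3, 1)
    closed = ndimage.binary_closing(main, structure=struct6,
                                    iterations=closing_iterations)
    interior = ndimage.binary_fill_holes(closed)
    voxel_um3 = labels.voxel_volume_um3
    records: list[InclusionRecord] = []
    next_id = 1
    for lab, cls in sorted(labels.label_table.items()):
        if lab == microglia_id or cls == "background":
            continue
        material = grid == lab
        if not (material & interior).any():
            continue
        comps, n = ndimage.label(material, structure=_STRUCT26)
        for c in range(1, n + 1):
            comp = comps == c
            inside = comp & interior
            if not inside.any():
                continue
            complete = bool(np.all(interior[comp]))
            coords = np.argwhere(inside)
            vol = float(inside.sum()) * voxel_um3
            records.append(
                InclusionRecord(
                    inclusion_id=next_id,
                    volume_um3=vol,
                    equivalent_diameter_nm=equivalent_diameter(vol),
                    completeness="complete" if complete else "partial",
                    source=_FOREIGN_SOURCES.get(cls, "undetermined"),
                    voxel_count=int(inside.sum()),
                    max_feret_nm=(
                        _max_feret_nm(coords, labels.voxel_spacing_nm)
                        if compute_feret else None
                    ),
                )
            )
            next_id += 1
    # self-engulfment: detached same-label fragments inside the main body
    for c in range(1, n_cell + 1):
        comp = cell_comps == c
        if bool((comp & main).any()):
            continue
        inside = comp & interior
        if not inside.any():
            continue
        vol = float(inside.sum()) * voxel_um3
        records.append(
            InclusionRecord(
                inclusion_id=next_id,
                volume_um3=vol,
                equivalent_diameter_nm=equivalent_diameter(vol),
                completeness="complete" if bool(np.all(interior[comp])) else "partial",
                source="self",
                voxel_count=int(inside.sum()),
                max_feret_nm=(
                    _max_feret_nm(np.argwhere(inside), labels.voxel_spacing_nm)
                    if compute_feret else None
                ),
            )
        )
        next_id += 1
    return records


def classify_completeness(record: InclusionRecord) -> str:
    return record.completeness


def size_distribution(records: list[InclusionRecord],
                      bin_width_um3: float = 0.005,
                      max_volume_um3: float = 0.1) -> dict:
    """Histogram over fixed volume bins plus mean diameter ± SEM."""
    if not records:
        raise ValueError("no inclusion records")
    volumes = np.asarray([r.volume_um3 for r in records])
    diameters = np.asarray([r.equivalent_diameter_nm for r in records])
    edges = np.arange(0.0, max_volume_um3 + bin_width_um3 / 2, bin_width_um3)
    counts, edges = np.histogram(np.clip(volumes, 0, max_volume_um3 - 1e-12),
                                 bins=edges)
    sem = (
        float(diameters.std(ddof=1) / math.sqrt(len(diameters)))
        if len(diameters) > 1 else 0.0
    )
    return {
        "bin_edges_um3": edges,
        "counts": counts,
        "mean_diameter_nm": float(diameters.mean()),
        "sem_diameter_nm": sem,
        "n": len(records),
    }


def records_to_frame(records: list[InclusionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
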