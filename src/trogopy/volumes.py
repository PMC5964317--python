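"""In-memory containers for raster data.

Axis convention (fixed package-wide): time-lapse grids are ``(t, channel,
z, y, x)``; single-timepoint label/mask grids are ``(z, y, x)`` or
``(t, z, y, x)``. ``z`` is the coarse (axial) axis. Voxel spacing is given
in nanometres per axis in ``(z, y, x)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: object classes a label id may map to
LABEL_CLASSES = frozenset(
    {"microglia", "dendrite", "spine", "axon", "bouton", "inclusion", "background"}
)


@dataclass
class TimeLapseVolume:
    """Multi-channel 3D time-lapse intensity grid.

    Parameters
    ----------
    data:
        Array of shape ``(t, channel, z, y, x)``.
    voxel_spacing_nm:
        ``(z, y, x)`` spacing in nanometres, e.g. ``(480, 130, 130)``.
    frame_interval_s:
        Time between frames in seconds.
    channel_names:
        One name per channel, e.g. ``("microglia", "neuron", "presynaptic")``.
    """

    data: np.ndarray
    voxel_spacing_nm: tuple[float, float, float]
    frame_interval_s: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"expected (t, channel, z, y, x) grid, got {self.data.ndim} axes"
            )
        self.voxel_spacing_nm = tuple(float(s) for s in self.voxel_spacing_nm)
        if len(self.voxel_spacing_nm) != 3 or any(
            s <= 0 for s in self.voxel_spacing_nm
        ):
            raise ValueError("voxel_spacing_nm must be 3 positive values (z, y, x)")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_spacing_nm
        return z * y * x * 1e-9

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(t, z, y, x)`` grid for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[:, idx]


@dataclass
class LabelVolume:
    """Integer-labelled segmentation aligned to a :class:`TimeLapseVolume`.

    ``data`` is ``(z, y, x)`` or ``(t, z, y, x)``; label 0 is background and
    every nonzero label must appear in ``label_table`` mapping id -> object
    class.
    """

    data: np.ndarray
    voxel_spacing_nm: tuple[float, float, float]
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("label grid must be (z, y, x) or (t, z, y, x)")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(
                f"label grid must be integer-typed, got {self.data.dtype}"
            )
        self.voxel_spacing_nm = tuple(float(s) for s in self.voxel_spacing_nm)
        if any(s <= 0 for s in self.voxel_spacing_nm):
            raise ValueError("voxel spacing entries must be positive")
        self.label_table = {int(k): str(v) for k, v in self.label_table.items()}
        for lab, cls in self.label_table.items():
            if cls not in LABEL_CLASSES:
                raise ValueError(f"unknown object class {cls!r} for label {lab}")
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(
                f"labels present in volume but absent from table: {sorted(missing)}"
            )

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.voxel_spacing_nm
        return z * y * x * 1e-9


def anisotropic_spacing_um(spacing_nm: tuple[float, float, float]) -> np.ndarray:
    """``(z, y, x)`` spacing in micrometres as a float array."""
    return np.asarray(spacing_nm, dtype=float) / 1000.0
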