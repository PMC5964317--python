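"""Normalization, noise thresholding, crosstalk removal, drift correction.

The central rule, applied before any interaction analysis: noise is
measured outside the cell of interest and removed by thresholding at the
measured value plus 40% (multiplier 1.4). The same rule clears residual
microglial reporter signal out of the neuron channel inside microglia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .volumes import TimeLapseVolume


@dataclass(frozen=True)
class ThresholdRule:
    """Noise estimate plus a multiplier; default multiplier 1.4 (= +40%)."""

    noise_estimate: float
    multiplier: float = 1.4

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.noise_estimate < 0:
            raise ValueError("noise_estimate must be >= 0")

    @property
    def cutoff(self) -> float:
        return self.noise_estimate * self.multiplier


@dataclass
class DriftTrace:
    """Per-frame integer translation (dz, dy, dx) in voxels; frame 0 is zero."""

    shifts: np.ndarray  # (n_frames, 3) int

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 3:
            raise ValueError("shifts must be (n_frames, 3)")
        if np.any(self.shifts[0] != 0):
            raise ValueError("first-frame translation must be (0, 0, 0)")


def estimate_noise(volume_frame: np.ndarray, background_region: np.ndarray,
                   statistic: str = "mean",
                   object_mask: np.ndarray | None = None) -> float:
    """Noise level from a background region outside any object.

    ``background_region`` is a boolean mask; the statistic is the
    arithmetic mean by default (median available).
    """
    background_region = np.asarray(background_region, dtype=bool)
    if background_region.shape != volume_frame.shape:
        raise ValueError("background region shape does not match the frame")
    if not background_region.any():
        raise ValueError("background region is empty")
    if object_mask is not None and np.any(background_region & np.asarray(object_mask, bool)):
        raise ValueError("background region overlaps the object mask")
    values = np.asarray(volume_frame)[background_region]
    if statistic == "mean":
        return float(values.mean())
    if statistic == "median":
        return float(np.median(values))
    raise ValueError(f"unknown statistic {statistic!r}")


def apply_threshold(volume_frame: np.ndarray, rule: ThresholdRule) -> np.ndarray:
    """Boolean mask of voxels strictly above ``noise x multiplier``."""
    return np.asarray(volume_frame) > rule.cutoff


def remove_crosstalk(neuron_channel: np.ndarray, microglia_mask: np.ndarray,
                     rule: ThresholdRule) -> np.ndarray:
    """Zero sub-cutoff neuron-channel voxels inside the microglia mask.

    Voxels outside the mask are never altered; bright (above-cutoff)
    voxels inside the mask — genuine neuronal structure overlapping a
    microglia — are retained.
    """
    neuron_channel = np.asarray(neuron_channel)
    microglia_mask = np.asarray(microglia_mask, dtype=bool)
    if microglia_mask.shape != neuron_channel.shape:
        raise ValueError(
            f"mask shape {microglia_mask.shape} does not align with channel "
            f"shape {neuron_channel.shape}"
        )
    cleaned = neuron_channel.copy()
    kill = microglia_mask & (neuron_channel <= rule.cutoff)
    cleaned[kill] = 0
    return cleaned


def normalize_intensity(volume: np.ndarray, foreground_mask: np.ndarray) -> np.ndarray:
    """Divide by the mean masked foreground intensity (cross-dataset scale)."""
    foreground_mask = np.asarray(foreground_mask, dtype=bool)
    if not foreground_mask.any():
        raise ValueError("foreground mask is empty")
    scale = float(np.asarray(volume)[foreground_mask].mean())
    if scale == 0:
        raise ValueError("mean foreground intensity is zero")
    return np.asarray(volume) / scale


def correct_drift(timelapse: TimeLapseVolume, reference_channel: str
                  ) -> tuple[TimeLapseVolume, DriftTrace]:
    """Rigid integer-voxel drift correction against frame 0.

    Each frame of the reference channel is registered to frame 0 by phase
    correlation; the (negated) detected shift is applied to every channel
    by integer rolling. Returns the corrected time-lapse and the per-frame
    translations that were detected.
    """
    if timelapse.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    ref = timelapse.channel(reference_channel)
    if not np.any(ref[0]):
        raise ValueError("all-zero reference frame 0: correlation undefined")
    shifts = np.zeros((timelapse.n_frames, 3), dtype=int)
    corrected = timelapse.data.copy()
    for t in range(1, timelapse.n_frames):
        if not np.any(ref[t]):
            raise ValueError(f"all-zero reference frame {t}: correlation undefined")
        shift, _, _ = phase_cross_correlation(
            ref[0].astype(float), ref[t].astype(float), upsample_factor=1,
            normalization=None,
        )
        shift = np.round(shift).astype(int)
        shifts[t] = -shift  # drift applied to the frame
        for c in range(corrected.shape[1]):
            corrected[t, c] = np.roll(timelapse.data[t, c], shift, axis=(0, 1, 2))
    out = TimeLapseVolume(
        data=corrected,
        voxel_spacing_nm=timelapse.voxel_spacing_nm,
        frame_interval_s=timelapse.frame_interval_s,
        channel_names=timelapse.channel_names,
    )
    return out, DriftTrace(shifts)
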