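"""Synthetic 3D time-lapse scenes of microglia-synapse interactions.

The generator builds a geometric phantom (dendrite + spines, a ramified
microglia, presynaptic axons with boutons, optional phagosome-marker
puncta), scripts interaction events from configurable rates, and renders
the phantom through an acquisition model (anisotropic Gaussian PSF,
Poisson photon noise, Gaussian read noise on a camera baseline, optional
channel crosstalk). Every scripted event is recorded in a ground-truth
:class:`~trogopy.events.EventLog`, which is what makes each downstream
analysis stage independently verifiable.

Scripted phenomenology follows the live-imaging regime the package
targets: 130 nm lateral / 480 nm axial voxels, 45-90 s frames, 2-3 h
sessions, brief (minutes-scale) microglia-spine contacts, tens of process
extension/retraction events per cell per minute at ~2 µm/min, rare
engulfment (trogocytosis) events with minute-scale latency, spine head
filopodia of 0.4-3.1 µm, and sub-µm³ presynaptic inclusions.

Axis order is ``(t, channel, z, y, x)``; ``z`` is the coarse axial axis.
All phantom coordinates are nanometres in ``(z, y, x)`` order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .events import EventLog
from .volumes import TimeLapseVolume

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


# ---------------------------------------------------------------------------
# acquisition + grid


@dataclass(frozen=True)
class AcquisitionModel:
    """Optical/camera model used to render a phantom into intensities.

    Defaults emulate light-sheet acquisition with 130 nm lateral pixels,
    a 480 nm axial step and 90 s frames. ``photon_scale`` is the expected
    photon count at unit phantom intensity (``inf`` = noiseless);
    ``baseline`` is the camera offset that gives the background its
    nonzero mean, which is what the noise-plus-40% thresholding rule
    measures. ``crosstalk_fraction`` adds that fraction of the microglia
    occupancy into the neuron channel (residual reporter expression in
    microglia).
    """

    voxel_spacing_nm: tuple[float, float, float] = (480.0, 130.0, 130.0)
    frame_interval_s: float = 90.0
    psf_sigma_nm: tuple[float, float] = (550.0, 150.0)  # (axial, lateral)
    photon_scale: float = 500.0
    read_noise_sd: float = 5.0
    baseline: float = 100.0
    crosstalk_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_nm):
            raise ValueError("voxel spacings must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if any(s <= 0 for s in self.psf_sigma_nm):
            raise ValueError(f"psf_sigma_nm must be positive, got {self.psf_sigma_nm}")
        if not 0 <= self.crosstalk_fraction < 1:
            raise ValueError("crosstalk_fraction must be in [0, 1)")
        if self.read_noise_sd < 0 or self.baseline < 0:
            raise ValueError("read_noise_sd and baseline must be nonnegative")

    def noiseless(self) -> "AcquisitionModel":
        """Noiseless limit: vanishing PSF, infinite photons, no read noise."""
        return replace(
            self,
            psf_sigma_nm=(1e-6, 1e-6),
            photon_scale=math.inf,
            read_noise_sd=0.0,
            baseline=0.0,
        )


@dataclass(frozen=True)
class GridSpec:
    """Raster grid for a scene: shape (z, y, x), spacing, and timebase."""

    shape: tuple[int, int, int] = (16, 192, 192)
    voxel_spacing_nm: tuple[float, float, float] = (480.0, 130.0, 130.0)
    n_frames: int = 8
    frame_interval_s: float = 90.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or any(
            s <= 0 for s in self.voxel_spacing_nm
        ):
            raise ValueError("grid shape and spacing must be positive")
        if self.n_frames < 1 or self.frame_interval_s <= 0:
            raise ValueError("need n_frames >= 1 and a positive frame interval")

    @property
    def extent_nm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.voxel_spacing_nm)

    @property
    def center_nm(self) -> np.ndarray:
        return self.extent_nm / 2.0

    @property
    def session_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s


# ---------------------------------------------------------------------------
# event-script parameters

_WT_EVENTS_PER_3H = 1.5       # wild-type trogocytosis events/cell per 3 h
_MEAN_LATENCY_S = 360.0       # 6 min mean contact-to-internalization latency
_MEAN_CONTACT_S = 252.0       # 4.2 min mean microglia-spine contact


@dataclass(frozen=True)
class EventScriptParams:
    """Rates and probabilities that script the ground-truth events.

    Defaults are the study conditions the generator emulates: 26
    extension / 21 retraction events per cell per minute at 1.9 / 1.8
    µm/min, 4.2 min mean spine contacts, 1.5 engulfment events per cell
    per 3 h with 6 min mean latency, 9/11 partial (vs near-complete)
    engulfments, spine-head-filopodium (SHF) incidence 13/31 on contacted
    vs 7% on non-contacted spines, disappearance 3/31 and transient 4/31
    among contacted spines, SHF relocation 5/21 with 27 vs 12 min mean
    lifetimes, and 2.6 pre-existing inclusions per cell.
    """

    contact_rate_per_spine_per_hour: float = 2.0
    mean_contact_duration_s: float = _MEAN_CONTACT_S
    contact_duration_shape: float = 2.0
    engulfment_rate_per_cell_per_3h: float = _WT_EVENTS_PER_3H
    bouton_contact_rate_per_cell_per_3h: float = 2.0
    mean_latency_s: float = _MEAN_LATENCY_S
    partial_fraction: float = 9.0 / 11.0
    engulfed_fraction_partial: tuple[float, float] = (0.2, 0.6)
    engulfed_fraction_major: tuple[float, float] = (0.7, 0.9)
    initial_inclusions_mean: float = 2.6
    shf_probability_contacted: float = 13.0 / 31.0
    shf_probability_noncontacted: float = 0.07
    shf_relocation_probability: float = 5.0 / 21.0
    shf_mean_length_um: float = 1.5
    shf_length_sd_um: float = 0.6
    shf_length_bounds_um: tuple[float, float] = (0.4, 3.1)
    shf_lifetime_relocating_min: float = 27.0
    shf_lifetime_nonrelocating_min: float = 12.0
    shf_direction_jitter_deg: float = 15.0
    disappearance_probability_contacted: float = 3.0 / 31.0
    transient_probability_contacted: float = 4.0 / 31.0
    stretch_probability_contacted: float = 2.0 / 31.0
    extension_event_rate_per_min: float = 26.0
    retraction_event_rate_per_min: float = 21.0
    extension_speed_um_min: float = 1.9
    retraction_speed_um_min: float = 1.8
    speed_jitter_sigma: float = 0.15
    marker_apposed_fraction: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.contact_rate_per_spine_per_hour,
            self.engulfment_rate_per_cell_per_3h,
            self.bouton_contact_rate_per_cell_per_3h,
            self.extension_event_rate_per_min,
            self.retraction_event_rate_per_min,
        )
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be nonnegative")
        probs = (
            self.partial_fraction,
            self.shf_probability_contacted,
            self.shf_probability_noncontacted,
            self.shf_relocation_probability,
            self.disappearance_probability_contacted,
            self.transient_probability_contacted,
            self.stretch_probability_contacted,
            self.marker_apposed_fraction,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.shf_length_bounds_um
        if not 0 < lo <= hi:
            raise ValueError("invalid SHF length bounds")


@dataclass(frozen=True)
class SceneLayout:
    """Geometry of the phantom (radii in nm, lengths in µm).

    Tube and blob radii match the scale of the structures being emulated:
    dendrite shaft ~0.4 µm radius, spine necks ~0.1 µm, spine heads
    0.25-0.4 µm, microglia processes 0.15-0.4 µm tapering tubes, boutons
    ~0.4 µm, and a locally swollen process end (phagocytic bulge) where
    engulfed material is internalized.
    """

    soma_radius_nm: float = 2500.0
    n_motility_processes: int = 64
    process_radius_nm: float = 280.0
    process_length_range_um: tuple[float, float] = (5.0, 9.0)
    process_length_bounds_um: tuple[float, float] = (3.0, 11.0)
    dendrite_radius_nm: float = 400.0
    n_spines: int = 0
    spine_spacing_um: float = 2.0
    neck_radius_nm: float = 100.0
    neck_length_range_um: tuple[float, float] = (0.6, 1.4)
    head_radius_range_nm: tuple[float, float] = (250.0, 400.0)
    shf_radius_nm: float = 160.0
    n_axons: int = 0
    boutons_per_axon: int = 3
    axon_radius_nm: float = 120.0
    axon_intensity: float = 0.35
    bouton_radius_nm: float = 400.0
    engulf_bulge_radius_nm: float = 1250.0
    transfer_offset_um: float = 1.5
    include_marker: bool = False


@dataclass(frozen=True)
class SHFSpec:
    """Scripted spine head filopodium."""

    onset_frame: int
    length_nm: float
    direction: tuple[float, float, float]  # unit vector, (z, y, x)
    lifetime_frames: int
    relocates: bool


@dataclass
class SpineSpec:
    """Scripted spine: anchored on the dendrite, with a fate and optional SHF."""

    base_point_nm: np.ndarray
    direction: np.ndarray  # unit (z, y, x), dendrite -> head
    neck_length_nm: float
    head_radius_nm: float
    fate: str = "stable"  # stable | disappearing | transient
    present_from: int = 0
    present_until: int | None = None  # exclusive; None = end of session
    contact_windows: list[tuple[int, int]] = field(default_factory=list)
    shf: SHFSpec | None = None
    stretch_window: tuple[int, int] | None = None

    @property
    def head_center_nm(self) -> np.ndarray:
        return self.base_point_nm + self.direction * (
            self.neck_length_nm + self.head_radius_nm
        )


# ---------------------------------------------------------------------------
# rasterization primitives


def _stamp_sphere(grid: np.ndarray, spacing: np.ndarray, center_nm, radius_nm: float,
                  value: float = 1.0) -> None:
    center = np.asarray(center_nm, dtype=float)
    lo = np.maximum(np.floor((center - radius_nm) / spacing - 1), 0).astype(int)
    hi = np.minimum(
        np.ceil((center + radius_nm) / spacing + 1), np.asarray(grid.shape)
    ).astype(int)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) + 0.5) * spacing[0] - center[0]
    yy = (np.arange(lo[1], hi[1]) + 0.5) * spacing[1] - center[1]
    xx = (np.arange(lo[2], hi[2]) + 0.5) * spacing[2] - center[2]
    d2 = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(sub, np.where(d2 <= radius_nm**2, value, 0.0), out=sub)


def _stamp_tube(grid: np.ndarray, spacing: np.ndarray, p0_nm, p1_nm,
                radius_nm: float, value: float = 1.0) -> None:
    p0 = np.asarray(p0_nm, dtype=float)
    p1 = np.asarray(p1_nm, dtype=float)
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0.0:
        _stamp_sphere(grid, spacing, p0, radius_nm, value)
        return
    lo = np.maximum(
        np.floor((np.minimum(p0, p1) - radius_nm) / spacing - 1), 0
    ).astype(int)
    hi = np.minimum(
        np.ceil((np.maximum(p0, p1) + radius_nm) / spacing + 1),
        np.asarray(grid.shape),
    ).astype(int)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) + 0.5) * spacing[0] - p0[0]
    yy = (np.arange(lo[1], hi[1]) + 0.5) * spacing[1] - p0[1]
    xx = (np.arange(lo[2], hi[2]) + 0.5) * spacing[2] - p0[2]
    # parameter of the closest point on the segment, clipped to [0, 1]
    t = (
        zz[:, None, None] * v[0] + yy[None, :, None] * v[1] + xx[None, None, :] * v[2]
    ) / vv
    np.clip(t, 0.0, 1.0, out=t)
    d2 = (
        (zz[:, None, None] - t * v[0]) ** 2
        + (yy[None, :, None] - t * v[1]) ** 2
        + (xx[None, None, :] - t * v[2]) ** 2
    )
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    np.maximum(sub, np.where(d2 <= radius_nm**2, value, 0.0), out=sub)


# ---------------------------------------------------------------------------
# scene phantom


class ScenePhantom:
    """Geometric phantom with scripted per-frame primitives.

    Frames are rasterized lazily through :meth:`rasterize_frame`;
    ``events`` holds the scripted ground truth.
    """

    def __init__(self, grid: GridSpec, layout: SceneLayout,
                 channel_names: tuple[str, ...]):
        self.grid = grid
        self.layout = layout
        self.channel_names = channel_names
        # per-frame, per-channel primitive lists:
        # ("sphere", center, radius, value) | ("tube", p0, p1, radius, value)
        self._prims: list[dict[str, list[tuple]]] = [
            {c: [] for c in channel_names} for _ in range(grid.n_frames)
        ]
        self.events: EventLog = EventLog()
        self.soma_center_nm: np.ndarray | None = None
        self.spines: list[SpineSpec] = []
        self.bouton_centers_nm: dict[str, np.ndarray] = {}
        self.tip_directions: np.ndarray | None = None       # (n_tips, 3) unit
        self.tip_lengths_nm: np.ndarray | None = None       # (n_tips, n_frames)
        self.dendrite_axis_nm: tuple[np.ndarray, np.ndarray] | None = None

    def add(self, frame: int, channel: str, prim: tuple) -> None:
        self._prims[frame][channel].append(prim)

    def add_range(self, frames: range, channel: str, prim: tuple) -> None:
        for f in frames:
            self._prims[f][channel].append(prim)

    def rasterize_frame(self, t: int) -> dict[str, np.ndarray]:
        """Float occupancy grids (z, y, x) per channel at frame ``t``."""
        spacing = np.asarray(self.grid.voxel_spacing_nm)
        out: dict[str, np.ndarray] = {}
        for ch in self.channel_names:
            grid = np.zeros(self.grid.shape, dtype=np.float32)
            for prim in self._prims[t][ch]:
                if prim[0] == "sphere":
                    _, center, radius, value = prim
                    _stamp_sphere(grid, spacing, center, radius, value)
                else:
                    _, p0, p1, radius, value = prim
                    _stamp_tube(grid, spacing, p0, p1, radius, value)
            out[ch] = grid
        return out

    def mask_frame(self, t: int, channel: str) -> np.ndarray:
        return self.rasterize_frame(t)[channel] > 0

    def signature(self) -> list:
        """Deterministic structural summary (used to assert reproducibility)."""
        sig = []
        for fr in self._prims:
            for ch in sorted(fr):
                for prim in fr[ch]:
                    flat = [prim[0], ch]
                    for part in prim[1:]:
                        flat.extend(np.round(np.atleast_1d(part), 6).tolist())
                    sig.append(tuple(flat))
        return sig


class SceneSizeError(ValueError):
    """Grid too small for the requested geometry."""


# ---------------------------------------------------------------------------
# scripting helpers


def _band_directions(n: int, max_elevation_rad: float, rng) -> np.ndarray:
    """n well-spread unit vectors (z, y, x) within an elevation band."""
    # golden-angle spiral: evenly spaced elevations with ~137.5° azimuth
    # increments give a guaranteed pairwise angular separation, so tubes
    # stamped along these directions do not merge away from the soma
    smax = math.sin(max_elevation_rad)
    s = -smax + (np.arange(n) + 0.5) * 2 * smax / n
    az = (np.arange(n) * GOLDEN_ANGLE + rng.uniform(0, 2 * math.pi)) % (2 * math.pi)
    cos_e = np.sqrt(1 - s**2)
    return np.stack([s, cos_e * np.sin(az), cos_e * np.cos(az)], axis=1)


def _perp_jitter(direction: np.ndarray, angle_rad: float, rng,
                 in_plane: bool = False) -> np.ndarray:
    """Rotate ``direction`` by ``angle_rad`` about a random perpendicular axis.

    With ``in_plane`` the rotation stays in the lateral (y, x) plane: thin
    structures (necks, filopodia) are scripted near-lateral, where the
    coarse axial sampling can actually represent them.
    """
    d = direction / np.linalg.norm(direction)
    if in_plane:
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        c, s = math.cos(sign * angle_rad), math.sin(sign * angle_rad)
        return np.array(
            [d[0], c * d[1] - s * d[2], s * d[1] + c * d[2]]
        )
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    phi = rng.uniform(0, 2 * math.pi)
    perp = math.cos(phi) * e1 + math.sin(phi) * e2
    return math.cos(angle_rad) * d + math.sin(angle_rad) * perp


# ---------------------------------------------------------------------------
# build_scene


def build_scene(params: EventScriptParams, grid: GridSpec,
                layout: SceneLayout | None = None,
                rng_seed: int | None = None) -> ScenePhantom:
    """Script a scene and its ground-truth event log.

    The scene contains a microglia (soma plus radial motility processes
    and, where boutons/spines are present, interaction processes), and,
    depending on ``layout``, a spiny dendrite and presynaptic axons with
    boutons. Identical ``(params, grid, layout, seed)`` produce an
    identical scene.
    """
    layout = layout or SceneLayout()
    seed = params.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)

    extent = grid.extent_nm
    lateral_extent_um = min(extent[1], extent[2]) / 1000.0
    if lateral_extent_um < 20.0:
        raise SceneSizeError(
            f"grid lateral extent {lateral_extent_um:.1f} µm is below the "
            "required 20 µm (one dendrite plus one microglia)"
        )

    # only channels with content are carried (and rendered)
    channels = ["microglia"]
    if layout.n_spines > 0:
        channels.append("neuron")
    if layout.n_axons > 0:
        channels.append("presynaptic")
    if layout.include_marker:
        channels.append("marker")
    scene = ScenePhantom(grid, layout, tuple(channels))
    records: list[dict] = []
    eid = 0

    center = grid.center_nm.copy()
    # snap the scene plane onto a voxel-center z: structures thinner than
    # half the axial step (necks, filopodia) vanish if their axis falls on
    # a voxel boundary
    dz = grid.voxel_spacing_nm[0]
    center[0] = (round(center[0] / dz - 0.5) + 0.5) * dz
    has_dendrite = layout.n_spines > 0
    soma = center.copy()
    if has_dendrite:
        soma[1] = center[1] + 4500.0  # microglia above the dendrite
    scene.soma_center_nm = soma
    all_frames = range(grid.n_frames)
    for f in all_frames:
        scene.add(f, "microglia", ("sphere", soma.copy(), layout.soma_radius_nm, 1.0))

    interval_min = grid.frame_interval_s / 60.0
    session_h = grid.session_s / 3600.0

    # -- motility processes ------------------------------------------------
    n_tips = layout.n_motility_processes
    if n_tips > 0:
        lmin, lmax = (b * 1000.0 for b in layout.process_length_bounds_um)
        reach = layout.soma_radius_nm + lmax + 800.0
        lat_half = min(extent[1], extent[2]) / 2.0
        if has_dendrite:
            lat_half = min(lat_half, extent[1] - soma[1] - 800.0, soma[1] - 800.0)
        if reach > lat_half:
            raise SceneSizeError(
                f"microglia reach {reach / 1000:.1f} µm exceeds the available "
                f"lateral half-extent {lat_half / 1000:.1f} µm"
            )
        z_room = min(soma[0], extent[0] - soma[0]) - grid.voxel_spacing_nm[0]
        max_elev = math.asin(min(0.9, max(0.05, z_room / reach)))
        dirs = _band_directions(n_tips, max_elev, rng)
        base = rng.uniform(*[b * 1000.0 for b in layout.process_length_range_um],
                           size=n_tips)
        lengths = np.empty((n_tips, grid.n_frames))
        lengths[:, 0] = base
        headroom = 3000.0  # keep room for one full event before the clamp
        for f in range(grid.n_frames - 1):
            lengths[:, f + 1] = lengths[:, f]
            n_ext = rng.poisson(params.extension_event_rate_per_min * interval_min)
            n_ret = rng.poisson(params.retraction_event_rate_per_min * interval_min)
            # extensions go to tips with headroom below the length cap,
            # retractions to tips with room above the floor (a process at
            # its bound cannot move further that way); one event per tip
            # per interval
            can_ext = list(np.flatnonzero(lengths[:, f] < lmax - headroom))
            can_ret = list(np.flatnonzero(lengths[:, f] > lmin + headroom))
            rng.shuffle(can_ext)
            rng.shuffle(can_ret)
            assign: list[tuple[int, str]] = []
            used: set[int] = set()
            for pool, kind, want in ((can_ext, "extension", n_ext),
                                     (can_ret, "retraction", n_ret)):
                got = 0
                for tip in pool:
                    if got >= want:
                        break
                    if tip in used:
                        continue
                    used.add(tip)
                    assign.append((int(tip), kind))
                    got += 1
            for tip, kind in assign:
                speed = (
                    params.extension_speed_um_min
                    if kind == "extension"
                    else params.retraction_speed_um_min
                )
                disp = (
                    speed
                    * interval_min
                    * math.exp(rng.normal(-params.speed_jitter_sigma**2 / 2,
                                          params.speed_jitter_sigma))
                    * 1000.0
                )
                sign = 1.0 if kind == "extension" else -1.0
                new = float(np.clip(lengths[tip, f] + sign * disp, lmin, lmax))
                realized = abs(new - lengths[tip, f])
                lengths[tip, f + 1] = new
                if realized < 300.0:  # clamp swallowed the event
                    continue
                records.append(
                    dict(
                        event_id=eid, event_type=kind, object_ids=f"tip{tip}",
                        onset_frame=f, offset_frame=f + 1,
                        displacement_um=realized / 1000.0,
                        speed_um_min=realized / 1000.0 / interval_min,
                    )
                )
                eid += 1
        scene.tip_directions = dirs
        scene.tip_lengths_nm = lengths
        for f in all_frames:
            for i in range(n_tips):
                p1 = soma + dirs[i] * (layout.soma_radius_nm + lengths[i, f])
                scene.add(
                    f, "microglia",
                    ("tube", soma.copy(), p1, layout.process_radius_nm, 1.0),
                )

    # -- dendrite + spines -------------------------------------------------
    if has_dendrite:
        span = (layout.n_spines - 1) * layout.spine_spacing_um * 1000.0
        if span + 4000.0 > extent[2]:
            raise SceneSizeError(
                f"dendrite span {span / 1000 + 4:.1f} µm exceeds the grid x "
                f"extent {extent[2] / 1000:.1f} µm"
            )
        dend_y = soma[1] - 10000.0
        if dend_y < 1500.0:
            raise SceneSizeError("grid y extent too small for dendrite placement")
        p0 = np.array([center[0], dend_y, 1000.0])
        p1 = np.array([center[0], dend_y, extent[2] - 1000.0])
        scene.dendrite_axis_nm = (p0, p1)
        for f in all_frames:
            scene.add(f, "neuron", ("tube", p0, p1, layout.dendrite_radius_nm, 1.0))

        x0 = center[2] - span / 2.0
        for j in range(layout.n_spines):
            base = np.array([center[0], dend_y, x0 + j * layout.spine_spacing_um * 1000.0])
            neck_len = rng.uniform(*[v * 1000.0 for v in layout.neck_length_range_um])
            head_r = rng.uniform(*layout.head_radius_range_nm)

            # contact windows from a homogeneous per-spine contact process
            n_contacts = rng.poisson(
                params.contact_rate_per_spine_per_hour * session_h
            )
            windows: list[tuple[int, int]] = []
            for _ in range(n_contacts):
                dur_s = rng.gamma(
                    params.contact_duration_shape,
                    params.mean_contact_duration_s / params.contact_duration_shape,
                )
                dur_f = max(1, round(dur_s / grid.frame_interval_s))
                t0 = int(rng.integers(0, max(1, grid.n_frames - dur_f)))
                windows.append((t0, min(t0 + dur_f, grid.n_frames - 1)))
            windows = _merge_windows(windows)
            contacted = bool(windows)
            direction = np.array([0.0, 1.0, 0.0]) if contacted else np.array([0.0, -1.0, 0.0])
            direction = _perp_jitter(direction, abs(rng.normal(0, math.radians(8))), rng, in_plane=True)
            spine = SpineSpec(
                base_point_nm=base, direction=direction,
                neck_length_nm=neck_len, head_radius_nm=head_r,
            )

            # fate
            u = rng.uniform()
            if contacted and u < params.transient_probability_contacted:
                spine.fate = "transient"
                spine.present_from = int(rng.integers(1, max(2, grid.n_frames // 3)))
                spine.present_until = int(
                    rng.integers(2 * grid.n_frames // 3, grid.n_frames)
                )
            elif contacted and u < (
                params.transient_probability_contacted
                + params.disappearance_probability_contacted
            ):
                spine.fate = "disappearing"
                spine.present_until = int(
                    rng.integers(grid.n_frames // 2, grid.n_frames)
                )
            until = spine.present_until if spine.present_until is not None else grid.n_frames
            windows = [
                (max(a, spine.present_from), min(b, until - 1))
                for a, b in windows
                if min(b, until - 1) - max(a, spine.present_from) >= 0
            ]
            # disappearances are never scripted mid-contact (contact windows end first)
            if spine.present_until is not None:
                windows = [
                    (a, min(b, until - 2)) for a, b in windows if a <= until - 2
                ]
            spine.contact_windows = windows
            contacted = bool(windows)

            # SHF
            p_shf = (
                params.shf_probability_contacted
                if contacted
                else params.shf_probability_noncontacted
            )
            if rng.uniform() < p_shf and until - spine.present_from > 4:
                if contacted:
                    w = windows[int(rng.integers(len(windows)))]
                    onset = min(max(w[0] + 1, 2), until - 3)
                    toward = _perp_jitter(
                        np.array([0.0, 1.0, 0.0]),
                        abs(rng.normal(0, math.radians(params.shf_direction_jitter_deg))),
                        rng, in_plane=True,
                    )
                else:
                    lo = max(spine.present_from + 1, 2)
                    onset = int(rng.integers(lo, max(until - 3, lo + 1)))
                    az = rng.uniform(0, 2 * math.pi)
                    toward = np.array([0.0, math.sin(az), math.cos(az)])
                relocates = contacted and rng.uniform() < params.shf_relocation_probability
                mean_life = (
                    params.shf_lifetime_relocating_min
                    if relocates
                    else params.shf_lifetime_nonrelocating_min
                )
                life_f = max(
                    2, round(rng.gamma(3.0, mean_life / 3.0) * 60.0 / grid.frame_interval_s)
                )
                life_f = min(life_f, until - 1 - onset)
                lo, hi = params.shf_length_bounds_um
                length = float(
                    np.clip(
                        rng.normal(params.shf_mean_length_um, params.shf_length_sd_um),
                        lo, hi,
                    )
                ) * 1000.0
                if life_f >= 2:
                    spine.shf = SHFSpec(
                        onset_frame=onset, length_nm=length,
                        direction=tuple(toward), lifetime_frames=life_f,
                        relocates=relocates,
                    )
            if contacted and rng.uniform() < params.stretch_probability_contacted:
                w = windows[int(rng.integers(len(windows)))]
                spine.stretch_window = w
            scene.spines.append(spine)

            eid = _render_spine(scene, spine, j, records, eid, grid, layout)

        # interaction process + contact cap per contact window
        for j, spine in enumerate(scene.spines):
            for (a, b) in spine.contact_windows:
                head = spine.head_center_nm
                cap_dir = (soma - head) / np.linalg.norm(soma - head)
                cap_r = spine.head_radius_nm * 1.2
                cap_c = head + cap_dir * spine.head_radius_nm
                for f in range(a, b + 1):
                    scene.add(f, "microglia", ("sphere", cap_c, cap_r, 1.0))
                    scene.add(
                        f, "microglia",
                        ("tube", soma.copy(), cap_c, layout.process_radius_nm, 1.0),
                    )
                records.append(
                    dict(
                        event_id=eid, event_type="contact",
                        object_ids=f"spine{j}", onset_frame=a, offset_frame=b,
                        duration_s=(b - a + 1) * grid.frame_interval_s,
                        approach_dz=-cap_dir[0], approach_dy=-cap_dir[1],
                        approach_dx=-cap_dir[2],
                    )
                )
                eid += 1

    # -- axons, boutons, engulfment ---------------------------------------
    if layout.n_axons > 0:
        eid = _script_presynaptic(scene, params, grid, layout, soma, rng, records, eid)

    scene.events = EventLog.from_records(records)
    return scene


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not windows:
        return []
    windows = sorted(windows)
    merged = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(w) for w in merged]


def _render_spine(scene: ScenePhantom, spine: SpineSpec, idx: int,
                  records: list[dict], eid: int, grid: GridSpec,
                  layout: SceneLayout) -> int:
    """Stamp a spine's per-frame geometry and log fate/SHF ground truth."""
    until = spine.present_until if spine.present_until is not None else grid.n_frames
    head0 = spine.head_center_nm
    shf = spine.shf
    reloc_frame = None
    if shf is not None and shf.relocates:
        reloc_frame = shf.onset_frame + shf.lifetime_frames
    for f in range(spine.present_from, until):
        base = spine.base_point_nm
        stretch = (
            spine.stretch_window is not None
            and spine.stretch_window[0] <= f <= spine.stretch_window[1]
        )
        neck_len = spine.neck_length_nm * (1.6 if stretch else 1.0)
        head_c = base + spine.direction * (neck_len + spine.head_radius_nm)
        tip = None
        if shf is not None and shf.onset_frame <= f < shf.onset_frame + shf.lifetime_frames:
            grown = min(1.0, (f - shf.onset_frame + 1) / 2.0)
            tip = head0 + np.asarray(shf.direction) * shf.length_nm * grown
        if reloc_frame is not None and f >= reloc_frame:
            tip_full = head0 + np.asarray(shf.direction) * shf.length_nm
            # head relocated to the filopodium tip; old path persists as neck
            scene.add(f, "neuron", ("tube", base, head0, layout.neck_radius_nm, 1.0))
            scene.add(f, "neuron", ("tube", head0, tip_full, layout.neck_radius_nm, 1.0))
            scene.add(f, "neuron", ("sphere", tip_full, spine.head_radius_nm, 1.0))
            continue
        scene.add(f, "neuron", ("tube", base, head_c, layout.neck_radius_nm, 1.0))
        scene.add(f, "neuron", ("sphere", head_c, spine.head_radius_nm, 1.0))
        if tip is not None:
            scene.add(f, "neuron", ("tube", head_c, tip, layout.shf_radius_nm, 1.0))

    if spine.fate == "transient":
        records.append(
            dict(event_id=eid, event_type="appearance", object_ids=f"spine{idx}",
                 onset_frame=spine.present_from, offset_frame=spine.present_from)
        )
        eid += 1
    if spine.fate in ("transient", "disappearing"):
        records.append(
            dict(event_id=eid, event_type="disappearance", object_ids=f"spine{idx}",
                 onset_frame=until, offset_frame=until)
        )
        eid += 1
    if shf is not None:
        d = np.asarray(shf.direction)
        toward_mg = np.array([0.0, 1.0, 0.0])
        cosang = float(np.clip(d @ toward_mg, -1.0, 1.0))
        records.append(
            dict(
                event_id=eid, event_type="shf", object_ids=f"spine{idx}",
                onset_frame=shf.onset_frame,
                offset_frame=shf.onset_frame + shf.lifetime_frames,
                length_um=shf.length_nm / 1000.0,
                lifetime_min=shf.lifetime_frames * grid.frame_interval_s / 60.0,
                relocated=shf.relocates,
                angle_to_microglia_deg=math.degrees(math.acos(cosang)),
            )
        )
        eid += 1
    return eid


def _script_presynaptic(scene: ScenePhantom, params: EventScriptParams,
                        grid: GridSpec, layout: SceneLayout, soma: np.ndarray,
                        rng, records: list[dict], eid: int) -> int:
    """Axons with boutons, scripted bouton contacts, engulfment, inclusions."""
    extent = grid.extent_nm
    n_frames = grid.n_frames
    session_h = grid.session_s / 3600.0
    all_frames = range(n_frames)

    # axons parallel to x on the soma side opposite the dendrite
    bouton_ids: list[str] = []
    boutons: list[np.ndarray] = []
    for a in range(layout.n_axons):
        off_y = soma[1] + (6000.0 + 2500.0 * a) * (1 if a % 2 == 0 else -1)
        off_y = float(np.clip(off_y, 1200.0, extent[1] - 1200.0))
        off_z = float(
            np.clip(soma[0] + rng.uniform(-1500.0, 1500.0), 800.0, extent[0] - 800.0)
        )
        dz = grid.voxel_spacing_nm[0]
        off_z = (round(off_z / dz - 0.5) + 0.5) * dz  # keep thin shafts rasterizable
        p0 = np.array([off_z, off_y, 1000.0])
        p1 = np.array([off_z, off_y, extent[2] - 1000.0])
        for f in all_frames:
            scene.add(
                f, "presynaptic",
                ("tube", p0, p1, layout.axon_radius_nm, layout.axon_intensity),
            )
        # boutons spread along the axon with >= 5 µm separation so one
        # event's geometry cannot put a neighbouring bouton into contact
        span = extent[2] * 0.6
        slot = span / max(1, layout.boutons_per_axon)
        for b in range(layout.boutons_per_axon):
            jitter = rng.uniform(0.1, 0.9) * max(slot - 5000.0, 0.0)
            bx = extent[2] * 0.2 + b * slot + 2500.0 + jitter
            c = np.array([off_z, off_y, bx])
            bid = f"bouton{len(boutons)}"
            bouton_ids.append(bid)
            boutons.append(c)
            scene.bouton_centers_nm[bid] = c

    bouton_scale = {b: np.ones(n_frames) for b in bouton_ids}

    # engulfment events (Poisson per cell, normalized to a 3 h session)
    n_eng = rng.poisson(params.engulfment_rate_per_cell_per_3h * session_h / 3.0)
    n_eng = min(n_eng, len(boutons))
    eng_targets = rng.choice(len(boutons), size=n_eng, replace=False)
    # extra contacts that never internalize anything
    n_plain = rng.poisson(params.bouton_contact_rate_per_cell_per_3h * session_h / 3.0)
    free = [i for i in range(len(boutons)) if i not in set(eng_targets)]
    rng.shuffle(free)
    plain_targets = free[:n_plain]

    x_hat = np.array([0.0, 0.0, 1.0])

    def _contact_tube(bidx: int, f0: int, f1: int) -> np.ndarray:
        # approach the bouton perpendicular to its axon via a waypoint, so
        # the process never grazes neighbouring boutons on the same axon;
        # the final approach is purely lateral so transferred material
        # stays on the bouton's (voxel-center) z-plane and small blobs
        # remain rasterizable
        c = boutons[bidx]
        to_soma = soma - c
        perp = np.array([0.0, to_soma[1], 0.0])
        perp = perp / np.linalg.norm(perp)
        waypoint = c + perp * 3000.0
        d = -perp  # final approach direction (waypoint -> bouton)
        tip = c - d * (layout.bouton_radius_nm * 0.6)
        for f in range(f0, f1 + 1):
            scene.add(
                f, "microglia",
                ("tube", soma.copy(), waypoint, layout.process_radius_nm * 1.4, 1.0),
            )
            scene.add(
                f, "microglia",
                ("tube", waypoint, tip, layout.process_radius_nm * 1.4, 1.0),
            )
        return d

    for bidx in plain_targets:
        dur = max(2, round(rng.gamma(2.0, 180.0) / grid.frame_interval_s))
        t0 = int(rng.integers(0, max(1, n_frames - dur)))
        t1 = min(t0 + dur, n_frames - 1)
        _contact_tube(bidx, t0, t1)
        records.append(
            dict(event_id=eid, event_type="contact", object_ids=bouton_ids[bidx],
                 onset_frame=t0, offset_frame=t1,
                 duration_s=(t1 - t0 + 1) * grid.frame_interval_s)
        )
        eid += 1

    for bidx in eng_targets:
        lat_f = max(1, round(rng.exponential(params.mean_latency_s) / grid.frame_interval_s))
        t0 = int(rng.integers(0, max(1, n_frames - lat_f - 2)))
        ti = min(t0 + lat_f, n_frames - 2)
        # the process stays engaged after internalization: the swollen end
        # holding the new inclusion remains part of the cell
        t1 = n_frames - 1
        d = _contact_tube(bidx, t0, t1)
        major = rng.uniform() >= params.partial_fraction
        frac = float(
            rng.uniform(*params.engulfed_fraction_major)
            if major
            else rng.uniform(*params.engulfed_fraction_partial)
        )
        c = boutons[bidx]
        blob_c = c - d * layout.transfer_offset_um * 1000.0
        blob_r = layout.bouton_radius_nm * frac ** (1.0 / 3.0)
        bouton_scale[bouton_ids[bidx]][ti:] = (1.0 - frac) ** (1.0 / 3.0)
        for f in range(ti, n_frames):
            scene.add(
                f, "microglia",
                ("sphere", blob_c, layout.engulf_bulge_radius_nm, 1.0),
            )
            scene.add(f, "presynaptic", ("sphere", blob_c, blob_r, 1.0))
        records.append(
            dict(
                event_id=eid, event_type="contact", object_ids=bouton_ids[bidx],
                onset_frame=t0, offset_frame=t1,
                duration_s=(t1 - t0 + 1) * grid.frame_interval_s,
            )
        )
        eid += 1
        records.append(
            dict(
                event_id=eid, event_type="engulfment", object_ids=bouton_ids[bidx],
                onset_frame=t0, offset_frame=ti,
                latency_s=(ti - t0) * grid.frame_interval_s,
                engulfed_fraction=frac, residual_at_site=True,
            )
        )
        eid += 1

    # stamp boutons with their per-frame residual radius
    for bid, c in zip(bouton_ids, boutons):
        for f in all_frames:
            r = layout.bouton_radius_nm * bouton_scale[bid][f]
            if r > 40.0:
                scene.add(f, "presynaptic", ("sphere", c, r, 1.0))

    # pre-existing inclusions inside the soma, mutually separated so they
    # resolve as distinct puncta at this voxel size
    n_inc = rng.poisson(params.initial_inclusions_mean)
    placed: list[np.ndarray] = []
    for k in range(n_inc):
        r = rng.uniform(250.0, 380.0)
        c = None
        for _ in range(40):
            d = _band_directions(1, math.radians(60), rng)[0]
            cand = soma + d * rng.uniform(0.0, layout.soma_radius_nm - r - 900.0)
            if all(np.linalg.norm(cand - p) >= 1300.0 for p in placed):
                c = cand
                break
        if c is None:
            continue
        placed.append(c)
        for f in all_frames:
            scene.add(f, "presynaptic", ("sphere", c, r, 1.0))
        records.append(
            dict(
                event_id=eid, event_type="inclusion", object_ids=f"inclusion{k}",
                onset_frame=0, offset_frame=n_frames - 1,
                volume_um3=4.0 / 3.0 * math.pi * (r / 1000.0) ** 3,
            )
        )
        eid += 1
    return eid


# ---------------------------------------------------------------------------
# rendering


def render_timelapse(scene: ScenePhantom, acq: AcquisitionModel,
                     rng_seed: int = 0) -> TimeLapseVolume:
    """Render a scene through the acquisition model.

    Per frame and channel: anisotropic Gaussian blur of the phantom
    occupancy, optional neuron-channel crosstalk from the microglia
    occupancy, Poisson photon noise at ``photon_scale``, plus the camera
    ``baseline`` and Gaussian read noise. With ``photon_scale = inf``,
    zero read noise and vanishing PSF the output equals the phantom
    occupancy (plus baseline).
    """
    if tuple(scene.grid.voxel_spacing_nm) != tuple(acq.voxel_spacing_nm):
        raise ValueError(
            f"scene spacing {scene.grid.voxel_spacing_nm} != acquisition "
            f"spacing {acq.voxel_spacing_nm}"
        )
    if not math.isclose(scene.grid.frame_interval_s, acq.frame_interval_s):
        raise ValueError("scene and acquisition frame intervals disagree")
    rng = np.random.default_rng(rng_seed)
    sigma_vox = (
        acq.psf_sigma_nm[0] / acq.voxel_spacing_nm[0],
        acq.psf_sigma_nm[1] / acq.voxel_spacing_nm[1],
        acq.psf_sigma_nm[1] / acq.voxel_spacing_nm[2],
    )

    def _prim_key(prim) -> tuple:
        flat = [prim[0]]
        for part in prim[1:]:
            flat.extend(np.round(np.atleast_1d(part), 3).tolist())
        return tuple(flat)

    # most frames repeat the previous frame's geometry exactly (events are
    # sparse), so the blurred signal is cached per channel keyed on the
    # frame's primitive list
    blur_cache: dict[str, tuple[tuple, np.ndarray]] = {}
    frames = []
    for t in range(scene.grid.n_frames):
        raster = scene.rasterize_frame(t)
        keys = {
            ch: tuple(_prim_key(p) for p in scene._prims[t][ch])
            for ch in scene.channel_names
        }
        if acq.crosstalk_fraction > 0 and "neuron" in raster and "microglia" in raster:
            raster["neuron"] = raster["neuron"] + acq.crosstalk_fraction * raster["microglia"]
            keys["neuron"] = (keys["neuron"], keys["microglia"])
        chans = []
        for ch in scene.channel_names:
            cached = blur_cache.get(ch)
            if cached is not None and cached[0] == keys[ch]:
                signal = cached[1]
            else:
                signal = ndimage.gaussian_filter(raster[ch], sigma=sigma_vox,
                                                 truncate=3.0)
                blur_cache[ch] = (keys[ch], signal)
            if math.isfinite(acq.photon_scale):
                counts = np.zeros_like(signal, dtype=np.float32)
                nz = signal > 1e-6
                counts[nz] = rng.poisson(signal[nz] * acq.photon_scale)
            else:
                counts = signal.astype(np.float32)
            out = counts + np.float32(acq.baseline)
            if acq.read_noise_sd > 0:
                out = out + acq.read_noise_sd * rng.standard_normal(
                    out.shape, dtype=np.float32
                )
            chans.append(out.astype(np.float32))
        frames.append(np.stack(chans))
    return TimeLapseVolume(
        data=np.stack(frames),
        voxel_spacing_nm=acq.voxel_spacing_nm,
        frame_interval_s=acq.frame_interval_s,
        channel_names=scene.channel_names,
    )


def write_ground_truth(log: EventLog, path) -> None:
    """CSV dump of a ground-truth event log (sorted measurement columns)."""
    from .events import write_events

    write_events(log, path)
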