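"""Per-spine morphometric time series and contact-coupled dynamics.

For every spine contacted at least once by microglia the pipeline tracks,
per frame: spine length (geodesic, dendrite junction to the farthest
spine voxel), head size (integrated neuron-channel signal over the head),
and the extent of contact (fraction of above-threshold head voxels that
are also above threshold in the microglia channel). On top of these
series sit contact-interval statistics, fate classification
(disappearing / transient spines), bootstrap cross-correlation of the
contact extent with spine length, spine-head-filopodium (SHF) detection,
and circular direction statistics with an Anderson-Darling uniformity
test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .skeleton import ProcessSkeleton, geodesic_from, skeletonize


# ---------------------------------------------------------------------------
# containers


@dataclass
class SpineTrack:
    """Per-frame morphometric series for one spine.

    Frames are contiguous over the spine's lifetime; ``appeared_frame``
    / ``disappeared_frame`` are None when the spine spans the session
    boundary on that side.
    """

    spine_id: int | str
    frames: np.ndarray
    length_um: np.ndarray
    head_intensity: np.ndarray
    contact_extent: np.ndarray
    appeared_frame: int | None = None
    disappeared_frame: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if len(self.frames) and np.any(np.diff(self.frames) != 1):
            raise ValueError("track frames must be contiguous")
        for name in ("length_um", "head_intensity", "contact_extent"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != len(self.frames):
                raise ValueError(f"{name} length does not match frames")
            setattr(self, name, arr)
        if np.any(self.length_um < 0):
            raise ValueError("negative spine length")
        if np.any((self.contact_extent < 0) | (self.contact_extent > 1)):
            raise ValueError("contact_extent outside [0, 1]")


@dataclass
class SHFRecord:
    spine_id: int | str
    onset_frame: int
    offset_frame: int
    max_length_um: float
    direction: tuple[float, float, float]
    angle_to_microglia_deg: float
    relocated: bool
    lifetime_min: float


@dataclass
class CrossCorrProfile:
    """Mean lagged-correlation profile with bootstrap uncertainty.

    ``ci_lo``/``ci_hi`` are pointwise per-lag percentile intervals;
    ``band_lo``/``band_hi`` form a simultaneous (sup-norm) 95% band — the
    object to use for statements about the profile at all lags jointly.
    """

    lags: np.ndarray
    mean_r: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    n_boot: int
    rng_seed: int
    per_spine_r: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# per-frame morphometry


def _crop(mask: np.ndarray, pad: int = 1) -> tuple[tuple[slice, ...], np.ndarray]:
    """Bounding-box crop of a boolean mask (pad voxels of margin)."""
    coords = np.argwhere(mask)
    lo = np.maximum(coords.min(axis=0) - pad, 0)
    hi = np.minimum(coords.max(axis=0) + pad + 1, np.asarray(mask.shape))
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return sl, mask[sl]


def _head_region(mask: np.ndarray, spacing_nm, thickness_fraction: float = 0.55
                 ) -> np.ndarray:
    """Thickest part of a spine mask (the head) via the distance transform."""
    edt = ndimage.distance_transform_edt(mask, sampling=spacing_nm)
    peak = edt.max()
    return edt >= thickness_fraction * peak


def spine_metrics(spine_masks: np.ndarray, dendrite_mask: np.ndarray,
                  neuron_channel: np.ndarray, microglia_channel: np.ndarray,
                  microglia_cutoff: float,
                  spacing_nm: tuple[float, float, float],
                  spine_id: int | str = 0,
                  base_vox: tuple[int, int, int] | None = None) -> SpineTrack:
    """Measure one spine across a session.

    ``spine_masks`` is the per-frame boolean spine segmentation (already
    thresholded and separated from the dendrite); empty frames are
    allowed only as a leading/trailing run (appearance / disappearance).
    """
    n_frames = spine_masks.shape[0]
    nonempty = [t for t in range(n_frames) if spine_masks[t].any()]
    if not nonempty:
        raise ValueError("spine never present")
    first, last = nonempty[0], nonempty[-1]
    if nonempty != list(range(first, last + 1)):
        raise ValueError(
            "spine absent in a mid-session frame without a disappearance flag"
        )
    if base_vox is None:
        dden = ndimage.distance_transform_edt(~np.asarray(dendrite_mask, bool),
                                              sampling=spacing_nm)
    frames, lengths, heads, extents = [], [], [], []
    for t in range(first, last + 1):
        mask = np.asarray(spine_masks[t], bool)
        if base_vox is None:
            cand = np.argwhere(mask)
            seed_full = tuple(cand[np.argmin(dden[tuple(cand.T)])])
        else:
            seed_full = base_vox
        sl, sub = _crop(mask)
        seed = tuple(
            int(np.clip(b - s.start, 0, dim - 1))
            for b, s, dim in zip(seed_full, sl, sub.shape)
        )
        skel = skeletonize(sub, spacing_nm, soma_seed_vox=seed)
        length = float(np.max(skel.root_distance_nm)) / 1000.0
        head_sub = _head_region(sub, spacing_nm)
        head = np.zeros_like(mask)
        head[sl] = head_sub
        head_int = float(np.asarray(neuron_channel[t])[head].sum())
        mg_above = np.asarray(microglia_channel[t]) > microglia_cutoff
        extent = float(mg_above[head].mean())
        frames.append(t)
        lengths.append(length)
        heads.append(head_int)
        extents.append(extent)
    return SpineTrack(
        spine_id=spine_id,
        frames=np.asarray(frames),
        length_um=np.asarray(lengths),
        head_intensity=np.asarray(heads),
        contact_extent=np.asarray(extents),
        appeared_frame=first if first > 0 else None,
        disappeared_frame=last + 1 if last < n_frames - 1 else None,
    )


def extract_spine_masks(neuron_masks: np.ndarray,
                        dendrite_axis_nm: tuple[np.ndarray, np.ndarray],
                        spine_bases_nm: list[np.ndarray],
                        spacing_nm: tuple[float, float, float],
                        reach_nm: float = 6000.0,
                        shaft_radius_nm: tuple[float, float] = (700.0, 1800.0),
                        attach_max_nm: float = 1500.0) -> dict[int, np.ndarray]:
    """Per-spine (t, z, y, x) masks from a thresholded neuron channel.

    The dendritic shaft — an elliptic cylinder around the known dendrite
    axis, wider axially because the PSF smears the shaft much further in
    z than laterally — is removed; for each annotated spine base, the
    nearest remaining connected component within ``attach_max_nm`` of the
    base is taken as that spine, frame by frame. Mirrors the manual ROI
    annotation a time-lapse analysis starts from.
    """
    neuron_masks = np.asarray(neuron_masks, dtype=bool)
    spacing = np.asarray(spacing_nm, dtype=float)
    p0, p1 = (np.asarray(p, dtype=float) for p in dendrite_axis_nm)
    zz, yy, xx = np.meshgrid(
        *[np.arange(s) for s in neuron_masks.shape[1:]], indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1) * spacing + spacing / 2
    v = p1 - p0
    tpar = np.clip(((pts - p0) @ v) / (v @ v), 0, 1)
    offset = pts - (p0 + tpar[..., None] * v)
    r_lat, r_ax = shaft_radius_nm
    shaft = (
        offset[..., 0] ** 2 / r_ax**2
        + (offset[..., 1] ** 2 + offset[..., 2] ** 2) / r_lat**2
    ) <= 1.0
    struct = np.ones((3, 3, 3), dtype=bool)
    out: dict[int, np.ndarray] = {}
    for j, base in enumerate(spine_bases_nm):
        base = np.asarray(base, dtype=float)
        roi = np.linalg.norm(pts - base, axis=-1) <= reach_nm
        per_frame = []
        for t in range(neuron_masks.shape[0]):
            cand = neuron_masks[t] & roi & ~shaft
            lab, n = ndimage.label(cand, structure=struct)
            if n == 0:
                per_frame.append(np.zeros_like(cand))
                continue
            best, bd = None, np.inf
            for c in range(1, n + 1):
                comp = lab == c
                d = np.linalg.norm(pts[comp] - base, axis=-1).min()
                if d < bd:
                    best, bd = c, d
            per_frame.append(
                lab == best if bd < attach_max_nm else np.zeros_like(cand)
            )
        out[j] = np.stack(per_frame)
    return out


# ---------------------------------------------------------------------------
# fates + contacts


def classify_spine_fates(tracks: list[SpineTrack], n_frames: int) -> pd.DataFrame:
    """stable / disappeared / transient per spine, with contact flags."""
    rows = []
    for tr in tracks:
        appeared = tr.appeared_frame is not None
        gone = tr.disappeared_frame is not None
        if appeared and gone:
            fate = "transient"
        elif gone:
            fate = "disappeared"
        else:
            fate = "stable"
        rows.append(
            {
                "spine_id": tr.spine_id,
                "fate": fate,
                "contacted": bool((tr.contact_extent > 0).any()),
                "n_contact_frames": int((tr.contact_extent > 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def noncontacted_neighbors(positions_um: dict, contacted: dict,
                           radius_um: float = 4.0) -> list:
    """Non-contacted spines within dendrite-path distance of a contacted one."""
    out = []
    for sid, pos in positions_um.items():
        if contacted.get(sid):
            continue
        near = any(
            contacted.get(other) and abs(positions_um[other] - pos) < radius_um
            for other in positions_um
            if other != sid
        )
        if near:
            out.append(sid)
    return out


def contact_durations(tracks: list[SpineTrack], frame_interval_s: float,
                      extent_threshold: float = 0.0) -> pd.DataFrame:
    """Contiguous in-contact runs per spine, in minutes, plus re-contacts."""
    rows = []
    for tr in tracks:
        flags = tr.contact_extent > extent_threshold
        run_start = None
        n_runs = 0
        for i, f in enumerate(list(flags) + [False]):
            if f and run_start is None:
                run_start = i
            elif not f and run_start is not None:
                n_runs += 1
                rows.append(
                    {
                        "spine_id": tr.spine_id,
                        "onset_frame": int(tr.frames[run_start]),
                        "offset_frame": int(tr.frames[i - 1]),
                        "duration_min": (i - run_start) * frame_interval_s / 60.0,
                    }
                )
                run_start = None
        for row in rows:
            if row["spine_id"] == tr.spine_id:
                row["n_contacts_for_spine"] = n_runs
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-correlation with bootstrap


def _lagged_corr(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """Pearson correlation of x(t) with y(t + lag)."""
    if lag >= 0:
        a, b = x[: len(x) - lag or None], y[lag:]
    else:
        a, b = x[-lag:], y[: len(y) + lag]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def cross_correlate(tracks: list[SpineTrack], max_lag: int,
                    n_boot: int = 1000, rng_seed: int = 0,
                    length_mode: str = "centered") -> CrossCorrProfile:
    """Cross-correlation of contact extent with spine-length variation.

    Per spine, the Pearson correlation between the contact-extent series
    and the (mean-centered, or first-differenced) length series at every
    lag in [-max_lag, +max_lag]; the profile is the across-spine mean
    with a percentile bootstrap CI obtained by resampling spines with
    replacement (respecting within-spine autocorrelation).
    """
    if len(tracks) < 3:
        raise ValueError("need at least 3 spine tracks")
    need = 2 * max_lag + 5
    per_spine = []
    for tr in tracks:
        if len(tr.frames) < need:
            raise ValueError(
                f"track {tr.spine_id}: {len(tr.frames)} frames < required {need}"
            )
        x = tr.contact_extent - tr.contact_extent.mean()
        if length_mode == "centered":
            y = tr.length_um - tr.length_um.mean()
        elif length_mode == "difference":
            y = np.diff(tr.length_um)
            x = x[:-1]
        else:
            raise ValueError(f"unknown length_mode {length_mode!r}")
        if x.std() == 0 or y.std() == 0:
            warnings.warn(
                f"spine {tr.spine_id}: constant series excluded", stacklevel=2
            )
            continue
        per_spine.append(
            [_lagged_corr(x, y, k) for k in range(-max_lag, max_lag + 1)]
        )
    if not per_spine:
        raise ValueError("all tracks excluded (constant series)")
    per_spine = np.asarray(per_spine)
    mean_r = np.nanmean(per_spine, axis=0)
    rng = np.random.default_rng(rng_seed)
    n = len(per_spine)
    boots = np.empty((n_boot, per_spine.shape[1]))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[i] = np.nanmean(per_spine[idx], axis=0)
    ci_lo = np.percentile(boots, 2.5, axis=0)
    ci_hi = np.percentile(boots, 97.5, axis=0)
    # simultaneous band: 95th percentile of the max absolute deviation of
    # bootstrap profiles from the point estimate
    dev = np.nanmax(np.abs(boots - mean_r), axis=1)
    q = float(np.percentile(dev, 95.0))
    return CrossCorrProfile(
        lags=np.arange(-max_lag, max_lag + 1),
        mean_r=mean_r, ci_lo=ci_lo, ci_hi=ci_hi,
        band_lo=mean_r - q, band_hi=mean_r + q,
        n_boot=n_boot, rng_seed=rng_seed, per_spine_r=per_spine,
    )


# ---------------------------------------------------------------------------
# spine head filopodia


def detect_shf(spine_masks: np.ndarray,
               spacing_nm: tuple[float, float, float],
               frame_interval_s: float,
               base_vox: tuple[int, int, int],
               spine_id: int | str = 0,
               min_shf_length_um: float = 0.4,
               min_absent_frames: int = 2,
               min_persist_frames: int = 2,
               relocate_tol_um: float = 0.6,
               microglia_direction: tuple[float, float, float] | None = None
               ) -> list[SHFRecord]:
    """Detect filopodia protruding from a spine head.

    An SHF is a skeleton endpoint whose along-skeleton distance from the
    head exceeds ``min_shf_length_um``, absent in the preceding
    ``min_absent_frames`` frames. The head is located per frame as the
    thickest region of the spine mask (distance-transform peak), which
    also yields relocation: the record is flagged relocated when the head
    centroid later sits at the filopodium tip, displaced by at least 70%
    of the branch length.
    """
    spacing = np.asarray(spacing_nm, dtype=float)
    n_frames = spine_masks.shape[0]
    tip_len: list[float] = []          # candidate branch length per frame (0 = none)
    tip_pos: list[np.ndarray | None] = []
    head_pos: list[np.ndarray | None] = []
    for t in range(n_frames):
        mask = np.asarray(spine_masks[t], bool)
        if not mask.any():
            tip_len.append(0.0)
            tip_pos.append(None)
            head_pos.append(None)
            continue
        sl, sub = _crop(mask)
        origin_nm = np.array([s.start for s in sl]) * spacing
        seed = tuple(
            int(np.clip(b - s.start, 0, dim - 1))
            for b, s, dim in zip(base_vox, sl, sub.shape)
        )
        skel = skeletonize(sub, spacing_nm, soma_seed_vox=seed)
        head = _head_region(sub, spacing_nm)
        hc = np.asarray(ndimage.center_of_mass(head)) * spacing + origin_nm
        head_pos.append(hc)
        # skeleton node closest to the head centroid
        node_nm = skel.node_nm(np.arange(len(skel.coords))) + origin_nm
        head_node = int(np.argmin(np.linalg.norm(node_nm - hc, axis=1)))
        from_head = geodesic_from(skel, head_node)
        tips = skel.tips
        if not len(tips):
            tip_len.append(0.0)
            tip_pos.append(None)
            continue
        # farthest endpoint beyond the head
        dists = from_head[tips]
        best = int(np.argmax(dists))
        if dists[best] >= min_shf_length_um * 1000.0:
            tip_len.append(float(dists[best]) / 1000.0)
            tip_pos.append(skel.node_nm(tips[best]) + origin_nm)
        else:
            tip_len.append(0.0)
            tip_pos.append(None)

    records: list[SHFRecord] = []
    t = 0
    while t < n_frames:
        if tip_len[t] <= 0:
            t += 1
            continue
        # require min_absent_frames clean frames among the recent window,
        # tolerating one spurious flicker frame
        prior = tip_len[max(0, t - (min_absent_frames + 1)):t]
        if (
            len(prior) < min_absent_frames
            or sum(v > 0 for v in prior) > len(prior) - min_absent_frames
        ):
            t += 1
            continue
        onset = t
        origin = (
            head_pos[onset - 1]
            if onset > 0 and head_pos[onset - 1] is not None
            else head_pos[onset]
        )
        last = t
        max_len = 0.0
        best_tip = tip_pos[t]
        relocated = False
        reloc_frame = None
        f = t
        while f < n_frames and tip_len[f] > 0:
            # branch length measured straight from the pre-onset head
            # position to the branch tip (robust to the skeleton's path
            # through the head blob)
            eucl = float(np.linalg.norm(tip_pos[f] - origin)) / 1000.0
            if eucl >= max_len:
                max_len = eucl
                best_tip = tip_pos[f]
            hp = head_pos[f]
            if (
                hp is not None
                and np.linalg.norm(hp - best_tip) <= relocate_tol_um * 1000.0
                and np.linalg.norm(hp - origin) >= 0.7 * max_len * 1000.0
            ):
                relocated = True
                reloc_frame = f
                break
            last = f
            f += 1
        if not relocated:
            # relocation collapses the branch (the head sits at its tip),
            # so also look just past the branch's disappearance
            for g in range(last + 1, min(last + 1 + min_absent_frames, n_frames)):
                hp = head_pos[g]
                if (
                    hp is not None
                    and np.linalg.norm(hp - best_tip) <= relocate_tol_um * 1000.0
                    and np.linalg.norm(hp - origin) >= 0.7 * max_len * 1000.0
                ):
                    relocated = True
                    reloc_frame = g
                    break
        if relocated:
            offset = int(reloc_frame)
        elif last + 1 < n_frames:
            offset = last + 1   # first frame the branch is gone
        else:
            offset = last       # right-censored at the session end
        if not relocated and (last - onset + 1) < min_persist_frames:
            # single-frame flicker, not a filopodium
            t = last + 1
            continue
        direction = best_tip - origin
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else direction
        if microglia_direction is not None:
            mg = np.asarray(microglia_direction, dtype=float)
            mg = mg / np.linalg.norm(mg)
            angle = math.degrees(math.acos(float(np.clip(direction @ mg, -1, 1))))
        else:
            angle = float("nan")
        records.append(
            SHFRecord(
                spine_id=spine_id, onset_frame=onset, offset_frame=offset,
                max_length_um=float(max_len), direction=tuple(direction),
                angle_to_microglia_deg=angle, relocated=relocated,
                lifetime_min=(offset - onset) * frame_interval_s / 60.0,
            )
        )
        # resume scanning right after the branch; the absence precondition
        # prevents re-triggering on the same (or a relocated) branch
        t = max(offset, last) + 1
    return records


# ---------------------------------------------------------------------------
# direction statistics


def anderson_darling_uniform(angles_deg, domain: tuple[float, float] = (0.0, 180.0)
                             ) -> tuple[float, float]:
    """Anderson-Darling test of angles against uniformity on ``domain``.

    Returns ``(A2, p)`` where A² is the Anderson-Darling statistic for
    the fully specified uniform null and p comes from the standard
    asymptotic approximation of its limiting distribution.
    """
    angles = np.asarray(angles_deg, dtype=float)
    lo, hi = domain
    if angles.ndim != 1 or len(angles) < 3:
        raise ValueError("need at least 3 angles")
    if np.any((angles < lo) | (angles > hi)):
        raise ValueError(f"angles outside [{lo}, {hi}]")
    n = len(angles)
    u = np.sort((angles - lo) / (hi - lo))
    eps = np.finfo(float).eps
    u = np.clip(u, eps, 1 - eps)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1])))
    return float(a2), float(_ad_sf(float(a2)))


def _ad_sf(z: float) -> float:
    """Upper tail of the limiting Anderson-Darling distribution
    (Marsaglia & Marsaglia's short-series approximation)."""
    if z <= 0:
        return 1.0
    if z < 2.0:
        cdf = (
            math.exp(-1.2337141 / z)
            / math.sqrt(z)
            * (2.00012 + (0.247105 - (0.0649821 - (0.0347962 - (0.011672
               - 0.00168691 * z) * z) * z) * z) * z)
        )
    else:
        cdf = math.exp(
            -math.exp(1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056
                      - 0.0003146 * z) * z) * z) * z) * z)
        )
    return min(max(1.0 - cdf, 0.0), 1.0)


def direction_statistics(shf_records: list[SHFRecord]) -> tuple[np.ndarray, float, float]:
    """Angles between SHF directions and their microglia process, with the
    Anderson-Darling uniformity test over [0°, 180°]."""
    angles = np.asarray(
        [r.angle_to_microglia_deg for r in shf_records if np.isfinite(
            r.angle_to_microglia_deg)]
    )
    a2, p = anderson_darling_uniform(angles)
    return angles, a2, p


# ---------------------------------------------------------------------------
# summaries


def summarize_spine_events(fates: pd.DataFrame, shf_spines: set,
                           stretch_spines: set | None = None,
                           group_column: str = "contacted") -> pd.DataFrame:
    """Percentages of disappeared / transient / SHF / stretching spines per
    group (contacted vs non-contacted), to one decimal."""
    stretch_spines = stretch_spines or set()
    rows = []
    for flag, name in ((True, "contacted"), (False, "non_contacted")):
        grp = fates[fates[group_column] == flag]
        if grp.empty:
            raise ValueError(f"empty group: {name}")
        n = len(grp)
        rows.append(
            {
                "group": name,
                "n": n,
                "disappeared_percent": round(
                    100.0 * (grp["fate"] == "disappeared").sum() / n, 1),
                "transient_percent": round(
                    100.0 * (grp["fate"] == "transient").sum() / n, 1),
                "shf_percent": round(
                    100.0 * grp["spine_id"].isin(shf_spines).sum() / n, 1),
                "stretching_percent": round(
                    100.0 * grp["spine_id"].isin(stretch_spines).sum() / n, 1),
            }
        )
    return pd.DataFrame(rows)


def compare_shf_lifetimes(records: list[SHFRecord]) -> dict:
    """Mean lifetime ± SEM (minutes) for relocating vs non-relocating SHFs."""
    reloc = [r.lifetime_min for r in records if r.relocated]
    non = [r.lifetime_min for r in records if not r.relocated]
    if not reloc and not non:
        raise ValueError("no SHF records")

    def _stats(vals):
        if not vals:
            return {"mean_min": None, "sem_min": None, "n": 0}
        arr = np.asarray(vals, dtype=float)
        sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else None
        return {"mean_min": float(arr.mean()), "sem_min": sem, "n": len(arr)}

    return {"relocating": _stats(reloc), "non_relocating": _stats(non)}
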