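"""Microglial process motility: extension/retraction events and speeds.

Process tips are matched between frames a fixed interval apart (1 min in
the emulated protocol); a matched tip whose along-skeleton soma-to-tip
length grows by more than a minimum displacement is an extension event,
one that shrinks is a retraction. New and lost tips are measured from
their branch point. Speeds are displacement over interval, in µm/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .skeleton import ProcessSkeleton

_BIG = 1e12


@dataclass(frozen=True)
class MotilityEvent:
    type: str                  # "extension" | "retraction"
    tip_id: int                # tip node index in the later frame (or earlier, for lost tips)
    displacement_um: float
    interval_s: float
    onset_frame: int = 0

    @property
    def speed_um_min(self) -> float:
        return self.displacement_um / (self.interval_s / 60.0)


def detect_motility_events(skeleton_t: ProcessSkeleton,
                           skeleton_t1: ProcessSkeleton,
                           interval_s: float = 60.0,
                           min_displacement_um: float = 0.26,
                           match_radius_um: float = 3.5,
                           onset_frame: int = 0) -> list[MotilityEvent]:
    """Match tips across two skeletons and emit motility events.

    Matching is a Hungarian assignment on physical tip-to-tip distance,
    gated at ``match_radius_um``. Relabelling the two frames swaps
    extension and retraction counts exactly.
    """
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    tips_a = skeleton_t.tips
    tips_b = skeleton_t1.tips
    events: list[MotilityEvent] = []
    min_nm = min_displacement_um * 1000.0

    matched_a: set[int] = set()
    matched_b: set[int] = set()
    if len(tips_a) and len(tips_b):
        pa = skeleton_t.node_nm(tips_a)
        pb = skeleton_t1.node_nm(tips_b)
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        cost = np.where(d <= match_radius_um * 1000.0, d, _BIG)
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] >= _BIG:
                continue
            matched_a.add(int(tips_a[i]))
            matched_b.add(int(tips_b[j]))
            # displacement magnitude = physical tip-to-tip distance (robust
            # to skeleton rerouting upstream of the tip); direction = sign
            # of the along-skeleton soma-to-tip length change
            disp = float(d[i, j])
            if disp <= min_nm:
                continue
            delta = (
                skeleton_t1.root_distance_nm[tips_b[j]]
                - skeleton_t.root_distance_nm[tips_a[i]]
            )
            events.append(
                MotilityEvent(
                    type="extension" if delta > 0 else "retraction",
                    tip_id=int(tips_b[j]),
                    displacement_um=disp / 1000.0,
                    interval_s=interval_s,
                    onset_frame=onset_frame,
                )
            )

    # new tips: extension from their branch point; lost tips: retraction to
    # it. A branch displacement beyond the matching gate cannot have grown
    # within one interval at these speeds and is discarded as a tracking
    # artifact rather than scored as an event.
    max_nm = match_radius_um * 1000.0
    for tip in tips_b:
        if int(tip) in matched_b:
            continue
        bp = skeleton_t1.branch_point_toward_root(int(tip))
        delta = skeleton_t1.root_distance_nm[tip] - skeleton_t1.root_distance_nm[bp]
        if min_nm < delta <= max_nm:
            events.append(
                MotilityEvent("extension", int(tip), float(delta) / 1000.0,
                              interval_s, onset_frame)
            )
    for tip in tips_a:
        if int(tip) in matched_a:
            continue
        bp = skeleton_t.branch_point_toward_root(int(tip))
        delta = skeleton_t.root_distance_nm[tip] - skeleton_t.root_distance_nm[bp]
        if min_nm < delta <= max_nm:
            events.append(
                MotilityEvent("retraction", int(tip), float(delta) / 1000.0,
                              interval_s, onset_frame)
            )
    return events


def summarize_motility(events: list[MotilityEvent], minutes_observed: float,
                       cell_id: int | str = 0) -> dict:
    """Per-cell event rates (events/cell/min) and mean speeds (µm/min).

    Speeds are reported as NaN (missing), never 0, when a direction has
    no events.
    """
    if minutes_observed <= 0:
        raise ValueError("zero observation time")
    ext = [e for e in events if e.type == "extension"]
    ret = [e for e in events if e.type == "retraction"]
    return {
        "cell_id": cell_id,
        "extension_rate_per_min": len(ext) / minutes_observed,
        "retraction_rate_per_min": len(ret) / minutes_observed,
        "mean_extension_speed_um_min": (
            float(np.mean([e.speed_um_min for e in ext])) if ext else float("nan")
        ),
        "mean_retraction_speed_um_min": (
            float(np.mean([e.speed_um_min for e in ret])) if ret else float("nan")
        ),
        "n_extension": len(ext),
        "n_retraction": len(ret),
    }


def summarize_motility_timepoints(events: list[MotilityEvent],
                                  frame_interval_s: float,
                                  cell_id: int | str = 0,
                                  timepoints_min: tuple[float, ...] = (0.0, 60.0, 120.0),
                                  window_min: float = 1.0) -> pd.DataFrame:
    """Rates/speeds in a short window at each requested session timepoint."""
    rows = []
    for tp in timepoints_min:
        f0 = tp * 60.0 / frame_interval_s
        f1 = (tp + window_min) * 60.0 / frame_interval_s
        sel = [e for e in events if f0 <= e.onset_frame < f1]
        row = summarize_motility(sel, window_min, cell_id)
        row["timepoint_min"] = tp
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison


def two_way_anova(df: pd.DataFrame, value: str, factor_a: str, factor_b: str
                  ) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction (type II sums of squares).

    Returns a table with rows for each main effect, the interaction, and
    the residual. Works on balanced and unbalanced layouts; a factorial
    cell with zero observations, or no residual degrees of freedom, is an
    error.
    """
    y = df[value].to_numpy(dtype=float)
    a = df[factor_a].astype("category")
    b = df[factor_b].astype("category")
    if a.cat.categories.size < 2 or b.cat.categories.size < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = pd.crosstab(a, b)
    if (counts == 0).to_numpy().any():
        empty = [(i, c) for i in counts.index for c in counts.columns
                 if counts.loc[i, c] == 0]
        raise ValueError(f"factorial cell(s) with zero observations: {empty}")

    def dummies(cat: pd.Series) -> np.ndarray:
        m = pd.get_dummies(cat, drop_first=True).to_numpy(dtype=float)
        return m

    one = np.ones((len(y), 1))
    da, db = dummies(a), dummies(b)
    dab = np.concatenate(
        [da[:, [i]] * db[:, [j]] for i in range(da.shape[1]) for j in range(db.shape[1])],
        axis=1,
    )

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    full = np.concatenate([one, da, db, dab], axis=1)
    rss_full = rss(full)
    df_err = len(y) - np.linalg.matrix_rank(full)
    if df_err <= 0:
        raise ValueError(
            "no residual degrees of freedom: the interaction term is "
            "undefined without replication"
        )
    ms_err = rss_full / df_err

    rows = []
    specs = {
        factor_a: (np.concatenate([one, db], axis=1),
                   np.concatenate([one, da, db], axis=1), da.shape[1]),
        factor_b: (np.concatenate([one, da], axis=1),
                   np.concatenate([one, da, db], axis=1), db.shape[1]),
        f"{factor_a}:{factor_b}": (np.concatenate([one, da, db], axis=1),
                                   full, dab.shape[1]),
    }
    for name, (reduced, augmented, dfe) in specs.items():
        ss = rss(reduced) - rss(augmented)
        F = (ss / dfe) / ms_err
        p = float(stats.f.sf(F, dfe, df_err))
        rows.append({"effect": name, "ss": ss, "df": dfe, "F": F, "p": p})
    rows.append({"effect": "residual", "ss": rss_full, "df": df_err,
                 "F": float("nan"), "p": float("nan")})
    return pd.DataFrame(rows)


def welch_t(group_a, group_b) -> dict:
    """Two-sided Welch t-test with Welch–Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0,
                "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                "sem_a": 0.0, "sem_b": 0.0}
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return {
        "t": float(res.statistic), "df": float(df), "p": float(res.pvalue),
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "sem_a": float(stats.sem(a)), "sem_b": float(stats.sem(b)),
    }


def compare_motility(df: pd.DataFrame, value: str = "rate",
                     time_factor: str = "time", direction_factor: str = "direction"
                     ) -> dict:
    """ANOVA table (main effects of time and direction) plus Welch t-tests."""
    table = two_way_anova(df, value, time_factor, direction_factor)
    ttests = {}
    levels = df[direction_factor].unique()
    if len(levels) == 2:
        ga = df.loc[df[direction_factor] == levels[0], value]
        gb = df.loc[df[direction_factor] == levels[1], value]
        if len(ga) >= 2 and len(gb) >= 2:
            ttests[f"{levels[0]}_vs_{levels[1]}"] = welch_t(ga, gb)
    return {"anova": table, "welch": ttests}
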