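"""Analytics for EB1-comet kymograph tracks and tubulin shrinkage events.

A comet track is the trajectory of a growing MT plus-end read off a
kymograph: ordered (time, position) points along the axon (cell body at
0 µm), with a direction of +1 for tip-ward growth (plus-end-out MT) and -1
for cell-body-ward growth (minus-end-out MT).  Tables are exchanged as long
CSV with columns ``axon_id, track_id, direction, t_s, x_um``; shrinkage
events as ``axon_id, t0_s, x0_um, t1_s, x1_um``.

The module applies the standard track-quality filters, estimates the axon
tip as the 0.95 quantile of comet positions, and computes per-axon growth
statistics -- added length per growth cycle d_g (µm/cycle), growth velocity
v_g (µm/min), catastrophe rate f_g (1/s) -- binned by distance from the tip
and split by growth direction, plus the orientation fraction (tip-ward
tracks / all tracks) and per-axon shrinkage lengths d_s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRACK_COLUMNS",
    "SHRINKAGE_COLUMNS",
    "DEFAULT_PIXEL_SIZE",
    "DEFAULT_FRAME_INTERVAL",
    "BootstrapCI",
    "filter_tracks",
    "axon_tip",
    "orientation_fraction",
    "growth_metrics",
    "shrinkage_metrics",
    "bootstrap_median_ci",
    "qc_axon",
    "per_axon_growth_summary",
]

TRACK_COLUMNS = ["axon_id", "track_id", "direction", "t_s", "x_um"]
SHRINKAGE_COLUMNS = ["axon_id", "t0_s", "x0_um", "t1_s", "x1_um"]

#: camera pixel size (µm) and acquisition interval (s); only filter rule (1)
#: depends on the pixel size, all other rules are in physical units.
DEFAULT_PIXEL_SIZE = 0.103
DEFAULT_FRAME_INTERVAL = 2.0

FILTER_RULES = {
    1: "net x-displacement < 2 pixels",
    2: "mean speed < 1.5 µm/min",
    3: "mean speed > 20 µm/min",
    4: "visible for < 4 frames",
}


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")


def _per_track(points: pd.DataFrame) -> pd.DataFrame:
    """One row per track: net displacement (µm), duration (s), speed (µm/min)."""
    g = points.sort_values("t_s").groupby(["axon_id", "track_id"], sort=False)
    first = g.first()
    last = g.last()
    out = pd.DataFrame(
        {
            "direction": first["direction"],
            "x_start": first["x_um"],
            "x_end": last["x_um"],
            "t_start": first["t_s"],
            "t_end": last["t_s"],
            "n_frames": g.size(),
        }
    )
    out["displacement_um"] = (out["x_end"] - out["x_start"]).abs()
    out["duration_s"] = out["t_end"] - out["t_start"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["speed_um_min"] = 60.0 * out["displacement_um"] / out["duration_s"]
    return out.reset_index()


def filter_tracks(
    tracks: pd.DataFrame,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four track-quality rules; return (survivors, removal log).

    A track is removed if (1) its net x-displacement is below two pixels,
    (2) its mean speed is below 1.5 µm/min, (3) its mean speed is above
    20 µm/min, or (4) it is visible for fewer than four frames.  The removal
    log has one row per rule with the number of tracks violating it (a track
    violating several rules is counted under each).
    """
    _require_columns(tracks, TRACK_COLUMNS, "track")
    if not pixel_size > 0 or not frame_interval > 0:
        raise ValueError("pixel_size and frame_interval must be > 0")
    if tracks.empty:
        log = pd.DataFrame(
            {"rule": list(FILTER_RULES), "description": list(FILTER_RULES.values()), "n_removed": 0}
        )
        return tracks.copy(), log

    per = _per_track(tracks)
    viol = {
        1: per["displacement_um"] < 2.0 * pixel_size,
        2: per["speed_um_min"] < 1.5,
        3: per["speed_um_min"] > 20.0,
        4: per["n_frames"] < 4,
    }
    removed = viol[1] | viol[2] | viol[3] | viol[4]
    bad = set(map(tuple, per.loc[removed, ["axon_id", "track_id"]].itertuples(index=False)))
    key = list(zip(tracks["axon_id"], tracks["track_id"]))
    survivors = tracks.loc[[k not in bad for k in key]].reset_index(drop=True)
    log = pd.DataFrame(
        {
            "rule": list(FILTER_RULES),
            "description": list(FILTER_RULES.values()),
            "n_removed": [int(viol[r].sum()) for r in FILTER_RULES],
        }
    )
    return survivors, log


def axon_tip(tracks: pd.DataFrame) -> float:
    """Axon tip position (µm): 0.95 quantile of all comet-point positions.

    The quantile guards against single outlier comets defining the tip; the
    linear-interpolation sample quantile (numpy default) is used.
    """
    _require_columns(tracks, ["x_um"], "track")
    if tracks.empty:
        raise ValueError("cannot locate the axon tip of an empty track table")
    return float(np.quantile(tracks["x_um"].to_numpy(), 0.95))


def orientation_fraction(tracks: pd.DataFrame) -> float:
    """Fraction of tracks growing tip-ward: (# direction=+1) / (# tracks).

    1 means a fully plus-end-out axon, 0.5 an equal mix.
    """
    _require_columns(tracks, ["axon_id", "track_id", "direction"], "track")
    per = tracks.drop_duplicates(["axon_id", "track_id"])
    if per.empty:
        raise ValueError("orientation fraction is undefined for an empty track table")
    return float((per["direction"] == 1).mean())


def growth_metrics(
    tracks: pd.DataFrame,
    tip: float | None = None,
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Per (distance-bin x direction) growth statistics.

    Each track contributes one growth event with d_g = |net displacement|
    (µm), a duration (s) and a speed (µm/min).  Events are assigned to
    10 µm bins of the distance from the axon tip of their *start* position
    (events starting beyond the tip clamp to bin 0).  Per bin and direction
    the table reports mean d_g (µm/cycle), mean v_g (µm/min),
    f_g = 1/(mean duration) (1/s) and the event count.  Bins without events
    are absent, not zero.
    """
    _require_columns(tracks, TRACK_COLUMNS, "track")
    if tracks.empty:
        raise ValueError("no tracks to compute growth metrics from")
    if tip is None:
        tip = axon_tip(tracks)
    per = _per_track(tracks)
    # distance from tip of the event's start, measured tip-ward
    dist = np.clip(tip - per["x_start"].to_numpy(), 0.0, None)
    per["dist_from_tip_um"] = dist
    per["bin"] = (dist // bin_width).astype(int)
    rows = []
    for (b, direction), grp in per.groupby(["bin", "direction"]):
        mean_dur = grp["duration_s"].mean()
        rows.append(
            {
                "bin": int(b),
                "bin_start_um": b * bin_width,
                "bin_end_um": (b + 1) * bin_width,
                "direction": int(direction),
                "d_g_um": grp["displacement_um"].mean(),
                "v_g_um_min": grp["speed_um_min"].mean(),
                "f_g_per_s": 1.0 / mean_dur if mean_dur > 0 else np.nan,
                "n_events": len(grp),
            }
        )
    return pd.DataFrame(rows).sort_values(["bin", "direction"]).reset_index(drop=True)


def per_axon_growth_summary(
    tracks: pd.DataFrame,
    tips: dict | None = None,
    near_tip_um: float = 10.0,
) -> pd.DataFrame:
    """One row per (axon, region, direction) with the axon's mean d_g etc.

    ``region`` is "near_tip" for events starting within ``near_tip_um`` of
    the axon tip and "shaft" otherwise; the per-axon value is the mean over
    that axon's events (across-axon medians are then taken with
    :func:`bootstrap_median_ci`).
    """
    _require_columns(tracks, TRACK_COLUMNS, "track")
    rows = []
    for axon_id, pts in tracks.groupby("axon_id"):
        tip = tips[axon_id] if tips is not None else axon_tip(pts)
        per = _per_track(pts)
        dist = np.clip(tip - per["x_start"], 0.0, None)
        per["region"] = np.where(dist <= near_tip_um, "near_tip", "shaft")
        for (region, direction), grp in per.groupby(["region", "direction"]):
            mean_dur = grp["duration_s"].mean()
            rows.append(
                {
                    "axon_id": axon_id,
                    "region": region,
                    "direction": int(direction),
                    "d_g_um": grp["displacement_um"].mean(),
                    "v_g_um_min": grp["speed_um_min"].mean(),
                    "f_g_per_s": 1.0 / mean_dur if mean_dur > 0 else np.nan,
                    "n_events": len(grp),
                }
            )
    return pd.DataFrame(rows)


def shrinkage_metrics(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-event shrinkage lengths d_s and per-axon means.

    Returns ``(per_event, per_axon)``; the per-event table adds
    ``d_s_um = |x1 - x0|``, the per-axon table holds the mean d_s and event
    count per axon.  Axons without events simply do not appear (flagged by
    absence).
    """
    _require_columns(events, SHRINKAGE_COLUMNS, "shrinkage")
    if events.empty:
        raise ValueError("no shrinkage events")
    per_event = events.copy()
    per_event["d_s_um"] = (per_event["x1_um"] - per_event["x0_um"]).abs()
    if (per_event["d_s_um"] <= 0).any():
        raise ValueError("shrinkage events must have positive length")
    if (per_event["t1_s"] <= per_event["t0_s"]).any():
        raise ValueError("shrinkage events must have end time after start time")
    per_axon = (
        per_event.groupby("axon_id")["d_s_um"].agg(["mean", "size"]).reset_index()
    )
    per_axon.columns = ["axon_id", "d_s_um", "n_events"]
    return per_event, per_axon


@dataclass(frozen=True)
class BootstrapCI:
    """Bootstrapped median with percentile 95% confidence bounds."""

    median: float
    lower: float
    upper: float
    n_resamples: int

    def __str__(self) -> str:
        return f"{self.median:.2f} [{self.lower:.2f}, {self.upper:.2f}]"


def bootstrap_median_ci(
    values, n_resamples: int = 10_000, seed: int | None = None
) -> BootstrapCI:
    """Percentile-bootstrap 95% CI of the median (10,000 resamples by default)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to bootstrap a median CI")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return BootstrapCI(
        median=float(np.median(values)),
        lower=float(lo),
        upper=float(hi),
        n_resamples=n_resamples,
    )


def qc_axon(orientation: float, mean_v_g_um_min: float) -> bool:
    """Control-axon quality gate.

    Fails (returns False) when the control axon's orientation fraction is
    below 0.8 or its average growth velocity is below 2 µm/min; a paired
    treatment axon inherits its control's flag.
    """
    return bool(orientation >= 0.8 and mean_v_g_um_min >= 2.0)
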