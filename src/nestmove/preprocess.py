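"""Filtering and regularization of raw Argos fixes and dive records.

The chain mirrors standard satellite-tag hygiene for this kind of study:
drop records without coordinates, duplicate timestamps, (optionally) fixes
on land, and fixes implying implausible speeds (> 20 km/h); keep contiguous
tracks with at most 12 h between fixes spanning at least 24 h; keep only
dives deeper than 10 m lasting longer than 20 s; then align both streams
onto the 6-hour model grid, expressing each fix as a fraction j of its
interval and assigning each dive to the interval containing it.

All operations take and return pandas DataFrames plus a removal report whose
counts partition the removed records (no double counting), and all are
idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ARGOS_CLASSES
from .tracks import INTERVAL_HOURS

EARTH_RADIUS_KM = 6371.0088

MAX_SPEED_KMH = 20.0
MAX_GAP_H = 12.0
MIN_SPAN_H = 24.0
MIN_DIVE_DEPTH_M = 10.0
MIN_DIVE_DURATION_S = 20.0

LandMask = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class RegularTrack:
    """One contiguous track segment aligned to the 6-h grid.

    Interval indices are 1-based; a fix in interval t sits at fraction
    ``j`` of the way from grid point t-1 to grid point t.  ``dive_order``
    is the 1-based within-interval dive counter u.
    """

    animal: str
    track_id: int
    t0: np.datetime64
    n_intervals: int
    fix_interval: np.ndarray
    fix_j: np.ndarray
    fix_x: np.ndarray
    fix_y: np.ndarray
    fix_class: np.ndarray
    dive_interval: np.ndarray
    dive_order: np.ndarray
    dive_depth: np.ndarray
    dive_duration: np.ndarray
    dive_time: np.ndarray
    n_dropped_dives: int = 0
    interval_hours: float = INTERVAL_HOURS


# ---------------------------------------------------------------------------
# reading & projection
# ---------------------------------------------------------------------------

def read_fixes(path) -> tuple[pd.DataFrame, dict]:
    """Read a fixes CSV; unparseable timestamps are rejected, not fatal."""
    df = pd.read_csv(path, dtype={"animal": str, "argos_class": str})
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True,
                        format="ISO8601").dt.tz_localize(None)
    bad = ts.isna()
    report = {"unparseable_timestamp": int(bad.sum())}
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    return df.reset_index(drop=True), report


def read_dives(path) -> tuple[pd.DataFrame, dict]:
    df = pd.read_csv(path, dtype={"animal": str})
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True,
                        format="ISO8601").dt.tz_localize(None)
    bad = ts.isna()
    report = {"unparseable_timestamp": int(bad.sum())}
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    return df.reset_index(drop=True), report


def project_to_plane(df: pd.DataFrame,
                     center: tuple[float, float] | None = None) -> pd.DataFrame:
    """Project geographic fixes (``lon``/``lat`` degrees) to planar km.

    Uses a spherical azimuthal-equidistant projection centered on the data
    centroid (or an explicit ``center=(lon0, lat0)``), which preserves
    distances from the center — adequate for regional tracking data.  Adds
    ``x_km``/``y_km`` columns; frames that already carry planar coordinates
    are returned unchanged.
    """
    if "x_km" in df.columns and "y_km" in df.columns:
        return df
    lon = np.radians(df["lon"].to_numpy(float))
    lat = np.radians(df["lat"].to_numpy(float))
    if center is None:
        lon0, lat0 = float(np.mean(lon)), float(np.mean(lat))
    else:
        lon0, lat0 = math.radians(center[0]), math.radians(center[1])
    dlam = lon - lon0
    cosc = np.clip(np.sin(lat0) * np.sin(lat)
                   + np.cos(lat0) * np.cos(lat) * np.cos(dlam), -1.0, 1.0)
    c = np.arccos(cosc)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(c), 1.0)
    out = df.copy()
    out["x_km"] = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlam)
    out["y_km"] = EARTH_RADIUS_KM * k * (np.cos(lat0) * np.sin(lat)
                                         - np.sin(lat0) * np.cos(lat) * np.cos(dlam))
    return out


# ---------------------------------------------------------------------------
# fix filtering
# ---------------------------------------------------------------------------

def clean_fixes(fixes: pd.DataFrame, land_mask: LandMask | None = None
                ) -> tuple[pd.DataFrame, dict]:
    """Drop fixes without coordinates, duplicate timestamps, unknown error
    classes, and (when a mask is supplied) locations on land.

    Among fixes sharing an (animal, timestamp) pair the first is kept.
    Report counts partition the removals by reason.
    """
    df = fixes.sort_values(["animal", "timestamp"], kind="stable").reset_index(drop=True)
    report = {"missing_coords": 0, "unknown_class": 0,
              "duplicate_timestamp": 0, "on_land": 0}
    if df.empty:
        return df, report

    missing = df["x_km"].isna() | df["y_km"].isna()
    report["missing_coords"] = int(missing.sum())
    df = df.loc[~missing]

    unknown = ~df["argos_class"].astype(str).isin(ARGOS_CLASSES)
    report["unknown_class"] = int(unknown.sum())
    df = df.loc[~unknown]

    dup = df.duplicated(subset=["animal", "timestamp"], keep="first")
    report["duplicate_timestamp"] = int(dup.sum())
    df = df.loc[~dup]

    if land_mask is not None and len(df):
        on_land = np.asarray(land_mask(df["x_km"].to_numpy(float),
                                       df["y_km"].to_numpy(float)), dtype=bool)
        report["on_land"] = int(on_land.sum())
        df = df.loc[~on_land]
    return df.reset_index(drop=True), report


def speed_filter(fixes: pd.DataFrame, max_speed: float = MAX_SPEED_KMH
                 ) -> tuple[pd.DataFrame, dict]:
    """Iteratively remove the later fix of any consecutive pair whose planar
    speed exceeds ``max_speed`` km/h, re-checking until no violation remains.

    Equivalent to a forward pass that compares each fix against the last
    retained one.
    """
    parts = []
    removed = 0
    for _, g in fixes.groupby("animal", sort=False):
        g = g.sort_values("timestamp", kind="stable")
        t = g["timestamp"].to_numpy("datetime64[s]").astype(float) / 3600.0
        x = g["x_km"].to_numpy(float)
        y = g["y_km"].to_numpy(float)
        keep = np.zeros(len(g), dtype=bool)
        if len(g):
            keep[0] = True
            last = 0
            for i in range(1, len(g)):
                dt = t[i] - t[last]
                dist = math.hypot(x[i] - x[last], y[i] - y[last])
                if dt > 0 and dist / dt <= max_speed:
                    keep[i] = True
                    last = i
        removed += int((~keep).sum())
        parts.append(g.loc[keep])
    out = pd.concat(parts).reset_index(drop=True) if parts else fixes.copy()
    return out, {"speed_violation": removed}


def segment_tracks(fixes: pd.DataFrame, max_gap: float = MAX_GAP_H,
                   min_span: float = MIN_SPAN_H) -> tuple[pd.DataFrame, dict]:
    """Split at inter-fix gaps > ``max_gap`` h and drop segments spanning
    < ``min_span`` h; adds a per-animal 1-based ``track`` column."""
    parts = []
    dropped_fixes = 0
    n_segments = 0
    for _, g in fixes.groupby("animal", sort=False):
        g = g.sort_values("timestamp", kind="stable")
        t = g["timestamp"].to_numpy("datetime64[s]").astype(float) / 3600.0
        seg = np.concatenate([[0], np.cumsum(np.diff(t) > max_gap)]) \
            if len(g) else np.zeros(0, dtype=int)
        track_no = 0
        for s in np.unique(seg):
            sub = g.loc[seg == s]
            span = (sub["timestamp"].iloc[-1] - sub["timestamp"].iloc[0]
                    ).total_seconds() / 3600.0
            if span < min_span:
                dropped_fixes += len(sub)
                continue
            track_no += 1
            n_segments += 1
            sub = sub.copy()
            sub["track"] = track_no
            parts.append(sub)
    if parts:
        out = pd.concat(parts).reset_index(drop=True)
    else:
        out = fixes.iloc[0:0].copy()
        out["track"] = pd.Series(dtype=int)
    return out, {"short_segment_fixes": dropped_fixes, "n_tracks": n_segments}


def filter_dives(dives: pd.DataFrame, min_depth: float = MIN_DIVE_DEPTH_M,
                 min_duration: float = MIN_DIVE_DURATION_S
                 ) -> tuple[pd.DataFrame, dict]:
    """Keep dives strictly deeper than ``min_depth`` m and strictly longer
    than ``min_duration`` s; negative values are rejected as invalid."""
    depth = dives["depth_m"].to_numpy(float)
    dur = dives["duration_s"].to_numpy(float)
    invalid = (depth < 0) | (dur < 0)
    shallow = ~invalid & (depth <= min_depth)
    short = ~invalid & ~shallow & (dur <= min_duration)
    keep = ~(invalid | shallow | short)
    report = {"invalid_record": int(invalid.sum()),
              "too_shallow": int(shallow.sum()),
              "too_short": int(short.sum())}
    return dives.loc[keep].reset_index(drop=True), report


def exclude_flagged(df: pd.DataFrame,
                    windows: Mapping[str, Sequence[tuple]] | None
                    ) -> tuple[pd.DataFrame, dict]:
    """Remove records inside user-supplied per-animal time windows.

    The study protocol removes migration legs (identified visually as
    unidirectional northward movement), so the exclusion is an explicit
    user decision, not a detector.  Overlapping windows are merged silently;
    window ends are inclusive.
    """
    if not windows:
        return df.reset_index(drop=True), {"flag_excluded": 0}
    drop = np.zeros(len(df), dtype=bool)
    ts = df["timestamp"].to_numpy("datetime64[s]")
    animals = df["animal"].to_numpy()
    for animal, spans in windows.items():
        merged = _merge_windows(spans)
        sel = animals == animal
        for lo, hi in merged:
            drop |= sel & (ts >= np.datetime64(lo, "s")) & (ts <= np.datetime64(hi, "s"))
    return df.loc[~drop].reset_index(drop=True), {"flag_excluded": int(drop.sum())}


def _merge_windows(spans: Iterable[tuple]) -> list[tuple]:
    spans = sorted((np.datetime64(a, "s"), np.datetime64(b, "s")) for a, b in spans)
    merged: list[list] = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------

def regularize(track: pd.DataFrame, dives: pd.DataFrame,
               interval_hours: float = INTERVAL_HOURS) -> RegularTrack:
    """Align one segmented track and its animal's dives onto the 6-h grid.

    The grid is anchored at the track's first fix.  Intervals are half-open
    [start, start + 6 h), except that a record at the final grid point
    closes the last interval (j = 1).  Dives outside the track's span are
    dropped (and counted), so every retained instant maps to exactly one
    interval.
    """
    track = track.sort_values("timestamp", kind="stable")
    animal = str(track["animal"].iloc[0])
    track_id = int(track["track"].iloc[0]) if "track" in track.columns else 1
    t0 = np.datetime64(track["timestamp"].iloc[0], "s")
    step_s = interval_hours * 3600.0
    span_s = float((np.datetime64(track["timestamp"].iloc[-1], "s") - t0)
                   / np.timedelta64(1, "s"))
    n_intervals = max(1, int(math.ceil(span_s / step_s - 1e-9)))

    def assign(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rel = (ts.astype("datetime64[s]") - t0).astype(float) / step_s
        t_idx = np.floor(rel).astype(np.int64) + 1
        j = rel - (t_idx - 1)
        at_end = t_idx == n_intervals + 1
        t_idx[at_end] = n_intervals
        j[at_end] = 1.0
        return t_idx, j

    f_idx, f_j = assign(track["timestamp"].to_numpy())

    d = dives[dives["animal"] == animal].sort_values("timestamp", kind="stable")
    ts = d["timestamp"].to_numpy("datetime64[s]")
    hi = t0 + np.timedelta64(int(n_intervals * step_s), "s")
    inside = (ts >= t0) & (ts <= hi)
    dropped = int((~inside).sum())
    d = d.loc[inside]
    d_idx, _ = assign(d["timestamp"].to_numpy())
    order = np.ones(len(d), dtype=np.int64)
    if len(d):
        order = d.groupby(d_idx).cumcount().to_numpy() + 1

    return RegularTrack(
        animal=animal, track_id=track_id, t0=t0, n_intervals=n_intervals,
        fix_interval=f_idx, fix_j=f_j,
        fix_x=track["x_km"].to_numpy(float), fix_y=track["y_km"].to_numpy(float),
        fix_class=track["argos_class"].astype(str).to_numpy(),
        dive_interval=d_idx, dive_order=order,
        dive_depth=d["depth_m"].to_numpy(float),
        dive_duration=d["duration_s"].to_numpy(float),
        dive_time=d["timestamp"].to_numpy("datetime64[s]"),
        n_dropped_dives=dropped, interval_hours=interval_hours,
    )


def preprocess(fixes: pd.DataFrame, dives: pd.DataFrame,
               land_mask: LandMask | None = None,
               exclusion_windows: Mapping[str, Sequence[tuple]] | None = None,
               max_speed: float = MAX_SPEED_KMH, max_gap: float = MAX_GAP_H,
               min_span: float = MIN_SPAN_H, min_depth: float = MIN_DIVE_DEPTH_M,
               min_duration: float = MIN_DIVE_DURATION_S,
               interval_hours: float = INTERVAL_HOURS
               ) -> tuple[list[RegularTrack], dict]:
    """Full chain: clean -> exclude -> speed filter -> segment -> dive filter
    -> regularize.  Returns the regular tracks and a nested removal report."""
    report: dict = {}
    fixes = project_to_plane(fixes)
    fixes, report["clean"] = clean_fixes(fixes, land_mask=land_mask)
    fixes, rep_f = exclude_flagged(fixes, exclusion_windows)
    dives, rep_d = exclude_flagged(dives, exclusion_windows)
    report["excluded"] = {"fixes": rep_f["flag_excluded"],
                          "dives": rep_d["flag_excluded"]}
    fixes, report["speed"] = speed_filter(fixes, max_speed=max_speed)
    fixes, report["segments"] = segment_tracks(fixes, max_gap=max_gap,
                                               min_span=min_span)
    dives, report["dives"] = filter_dives(dives, min_depth=min_depth,
                                          min_duration=min_duration)
    tracks = []
    if len(fixes):
        for (_, _), g in fixes.groupby(["animal", "track"], sort=True):
            tracks.append(regularize(g, dives, interval_hours=interval_hours))
    n_assigned = int(sum(t.dive_depth.size for t in tracks))
    report["regularized"] = {
        "n_tracks": len(tracks),
        "dives_assigned": n_assigned,
        "dives_unassigned": int(len(dives)) - n_assigned,
    }
    return tracks, report
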