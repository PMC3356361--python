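"""Glider-track vs satellite-tag encounter matching.

A tagged whale's ARGOS surfacing fixes are compared against the glider's
track: a fix marks a *potential encounter* when its reported accuracy
radius is small enough (<= 1.5 km by default) and the glider was within
a maximum range (6 km by default — the ~4 km theoretical detection limit
for beaked-whale clicks padded for tag-position uncertainty) at the fix
time.  The module also reconstructs a hypothetical whale dive profile
from fix times (deep dives only, surface intervals centred on the
fixes, whales silent above the vocal-onset depth) and intersects its
vocal intervals with the glider's recording intervals to explain missed
detections caused by the glider's intermittent duty cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "haversine_km",
    "DiveCycleParams",
    "find_potential_encounters",
    "hypothetical_dive_profile",
    "recording_intervals",
    "recording_overlap",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between (lat, lon) points (degrees).

    Raises
    ------
    ValueError
        For out-of-range coordinates.
    """
    for lat, lon in (p1, p2):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 360.0):
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    la1, lo1, la2, lo2 = map(math.radians, (*p1, *p2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    a = math.sin(dlat / 2) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


@dataclass(frozen=True)
class DiveCycleParams:
    """Mean dive-cycle parameters for the hypothetical whale profile.

    Defaults follow published mean deep-dive behaviour of Cuvier's
    beaked whales (~58 min foraging dives, ~2 min surfacings, descent
    1.1 m/s, ascent 0.8 m/s, vocal below ~400 m); they are configuration
    values, not survey measurements.
    """

    deep_dive_duration_s: float = 3480.0
    surface_duration_s: float = 120.0
    vocal_onset_depth_m: float = 400.0
    descent_rate_mps: float = 1.1
    ascent_rate_mps: float = 0.8
    max_depth_m: float = 1400.0

    def __post_init__(self) -> None:
        if min(self.deep_dive_duration_s, self.surface_duration_s) <= 0:
            raise ValueError("durations must be positive")
        if self.vocal_onset_depth_m <= 0:
            raise ValueError("vocal_onset_depth_m must be positive")


def _epoch_s(times) -> np.ndarray:
    return pd.to_datetime(pd.Series(list(times))).astype("int64").to_numpy() / 1e9


def interpolate_position(track: pd.DataFrame, when) -> tuple[float, float]:
    """Glider (lat, lon) at time ``when`` by linear interpolation."""
    tt = _epoch_s(track["time"])
    t = _epoch_s([when])[0]
    return (
        float(np.interp(t, tt, track["lat"].to_numpy())),
        float(np.interp(t, tt, track["lon"].to_numpy())),
    )


def find_potential_encounters(
    track: pd.DataFrame,
    fixes: pd.DataFrame,
    max_km: float = 6.0,
    max_acc_km: float = 1.5,
    mode: str = "interpolated",
    merge_gap_s: float = 24 * 3600.0,
) -> pd.DataFrame:
    """Identify potential glider-whale encounters from tag fixes.

    A fix qualifies iff its ``accuracy_radius_km`` <= ``max_acc_km`` and
    the glider-whale distance at the fix time is <= ``max_km``.  The
    glider position is linearly interpolated between track samples
    (``mode='interpolated'``) or taken from the nearest track sample
    (``mode='nearest'``).  Qualifying fixes closer together than
    ``merge_gap_s`` share an ``encounter_id``.  Fixes outside the track
    time span are skipped with a warning.

    Returns a DataFrame of qualifying fixes with glider position,
    distance and encounter id.
    """
    if len(track) == 0:
        raise ValueError("empty glider track")
    if mode not in ("interpolated", "nearest"):
        raise ValueError("mode must be 'interpolated' or 'nearest'")
    tt = _epoch_s(track["time"])
    rows = []
    for _, fix in fixes.iterrows():
        t = _epoch_s([fix["time"]])[0]
        if t < tt[0] or t > tt[-1]:
            log.warning("fix at %s outside track time span; skipped", fix["time"])
            continue
        if fix["accuracy_radius_km"] > max_acc_km:
            continue
        if mode == "interpolated":
            glat = float(np.interp(t, tt, track["lat"].to_numpy()))
            glon = float(np.interp(t, tt, track["lon"].to_numpy()))
        else:
            k = int(np.argmin(np.abs(tt - t)))
            glat = float(track["lat"].iloc[k])
            glon = float(track["lon"].iloc[k])
        d = haversine_km((glat, glon), (fix["lat"], fix["lon"]))
        if d <= max_km:
            rows.append(
                {
                    "time": fix["time"],
                    "whale_lat": fix["lat"],
                    "whale_lon": fix["lon"],
                    "glider_lat": glat,
                    "glider_lon": glon,
                    "distance_km": d,
                    "accuracy_radius_km": fix["accuracy_radius_km"],
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "time",
            "whale_lat",
            "whale_lon",
            "glider_lat",
            "glider_lon",
            "distance_km",
            "accuracy_radius_km",
        ],
    )
    if len(out):
        ts = _epoch_s(out["time"])
        eid = np.zeros(len(out), dtype=int)
        for i in range(1, len(out)):
            eid[i] = eid[i - 1] + (1 if ts[i] - ts[i - 1] > merge_gap_s else 0)
        out["encounter_id"] = eid
    else:
        out["encounter_id"] = pd.Series(dtype=int)
    return out


def hypothetical_dive_profile(
    fix_times: Sequence,
    params: DiveCycleParams = DiveCycleParams(),
    flank_dives: int = 1,
    dt_s: float = 10.0,
) -> tuple[pd.DataFrame, list[tuple[float, float]]]:
    """Reconstruct a deep-dives-only whale profile from surfacing times.

    Each fix marks the centre of a surface interval; between consecutive
    surfacings the whale performs one u-shaped deep dive (descent and
    ascent at the configured rates, flat bottom when the triangular
    profile would exceed ``max_depth_m``).  ``flank_dives`` adds that
    many standard-length dives before the first and after the last
    surfacing.  Returns ``(profile, vocal_intervals)`` where ``profile``
    has columns ``t_s`` (epoch seconds) and ``depth_m``, and
    ``vocal_intervals`` are (start, end) epoch-second pairs during which
    the whale is below the vocal-onset depth (silent on shallow dives
    and above it).

    Raises
    ------
    ValueError
        If no fix is given or consecutive surfacings leave no room for
        a dive between them.
    """
    if len(fix_times) == 0:
        raise ValueError("at least one fix time is required")
    centers = np.sort(_epoch_s(fix_times))
    half_surf = params.surface_duration_s / 2.0

    # surface intervals [start, end] centred on fixes
    surfs = [(c - half_surf, c + half_surf) for c in centers]
    dives: list[tuple[float, float]] = []
    for (s0, e0), (s1, _) in zip(surfs[:-1], surfs[1:]):
        if s1 - e0 <= 0:
            raise ValueError(
                "consecutive fixes closer than one surface interval; no room to dive"
            )
        dives.append((e0, s1))
    for k in range(flank_dives):
        first = surfs[0][0] - (k + 1) * (params.deep_dive_duration_s + params.surface_duration_s)
        dives.insert(0, (first + params.surface_duration_s,
                         first + params.surface_duration_s + params.deep_dive_duration_s))
        last = surfs[-1][1] + k * (params.deep_dive_duration_s + params.surface_duration_s)
        dives.append((last, last + params.deep_dive_duration_s))
    dives.sort()

    rd, ra = params.descent_rate_mps, params.ascent_rate_mps
    vocal: list[tuple[float, float]] = []
    t_grid: list[np.ndarray] = []
    d_grid: list[np.ndarray] = []
    for t0, t1 in dives:
        L = t1 - t0
        d_tri = L * rd * ra / (rd + ra)
        d_max = min(d_tri, params.max_depth_m)
        t_down = d_max / rd
        t_up = d_max / ra
        tt = np.arange(t0, t1 + dt_s, dt_s)
        rel = tt - t0
        depth = np.minimum(np.minimum(rel * rd, (L - rel) * ra), d_max)
        depth = np.maximum(depth, 0.0)
        t_grid.append(tt)
        d_grid.append(depth)
        vd = params.vocal_onset_depth_m
        if vd <= d_max:
            vocal.append((t0 + vd / rd, t1 - vd / ra))
        del t_down, t_up
    profile = pd.DataFrame(
        {"t_s": np.concatenate(t_grid), "depth_m": np.concatenate(d_grid)}
    ).sort_values("t_s", ignore_index=True)
    return profile, vocal


def recording_intervals(track: pd.DataFrame) -> list[tuple[float, float]]:
    """Contiguous (start, end) epoch-second intervals where the glider's
    acoustic system was recording."""
    tt = _epoch_s(track["time"])
    rec = track["recording"].to_numpy().astype(bool)
    out = []
    start = None
    for i, r in enumerate(rec):
        if r and start is None:
            start = tt[i]
        elif not r and start is not None:
            out.append((start, tt[i]))
            start = None
    if start is not None:
        out.append((start, tt[-1]))
    return out


def _as_seconds(iv) -> tuple[float, float]:
    a, b = iv
    if isinstance(a, (datetime, pd.Timestamp, str, np.datetime64)):
        a, b = _epoch_s([a, b])
    return float(a), float(b)


def recording_overlap(
    vocal_intervals: Sequence, recording: Sequence
) -> tuple[list[tuple[float, float]], float]:
    """Intersect whale-vocal intervals with glider recording intervals.

    Returns the overlap intervals (epoch seconds) and their total
    duration in seconds.
    """
    a = sorted(_as_seconds(iv) for iv in vocal_intervals)
    b = sorted(_as_seconds(iv) for iv in recording)
    out: list[tuple[float, float]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    total = float(sum(hi - lo for lo, hi in out))
    return out, total
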