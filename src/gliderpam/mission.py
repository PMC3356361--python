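"""Mission-level aggregation of per-file detection flags.

Turns a table of per-minute-file class flags (one row per recorded
1-minute file, boolean column per signal class, plus dive id and UTC
start time) into survey statistics: per-class file percentages, per-dive
summaries, diel (hour-of-day) activity profiles, a day/night one-way
ANOVA, encounter counting and encounter rates, and detector-performance
accounting against a ground-truth flag table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_with_class",
    "dive_summaries",
    "diel_profile",
    "one_way_anova",
    "day_night_anova",
    "Encounter",
    "count_encounters",
    "encounter_rate",
    "detector_performance",
    "write_report",
]

DAY_HOURS = tuple(range(7, 19))  # 07:00-18:00 local
NIGHT_HOURS = tuple(h % 24 for h in range(19, 31))  # 19:00-06:00 local


def percent_with_class(flags: pd.DataFrame, cls: str) -> float:
    """Percentage of analysed files whose ``cls`` flag is set.

    Raises
    ------
    ValueError
        For an empty flag table.
    """
    if len(flags) == 0:
        raise ValueError("empty flag table")
    return 100.0 * float(flags[cls].sum()) / float(len(flags))


def dive_summaries(
    flags: pd.DataFrame, classes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-dive file counts and percentages per class.

    ``flags`` needs ``dive_id`` plus boolean class columns (and
    optionally ``start_utc``, ``lat``, ``lon`` for dive metadata).
    """
    classes = list(classes) if classes is not None else [
        c for c in flags.columns if flags[c].dtype == bool
    ]
    rows = []
    for dive, grp in flags.groupby("dive_id"):
        row = {"dive_id": dive, "n_minute_files": len(grp)}
        if "start_utc" in grp:
            row["start_utc"] = grp["start_utc"].min()
            row["end_utc"] = grp["start_utc"].max()
        for col in ("lat", "lon"):
            if col in grp:
                row[f"mean_{col}"] = float(grp[col].mean())
        for c in classes:
            count = int(grp[c].sum())
            row[f"{c}_files"] = count
            row[f"{c}_pct"] = 100.0 * count / len(grp)
        rows.append(row)
    return pd.DataFrame(rows)


def _local_hour(start_utc: pd.Series, utc_offset_h: float) -> pd.Series:
    t = pd.to_datetime(start_utc)
    return ((t + pd.to_timedelta(utc_offset_h, unit="h")).dt.hour).astype(int)


def diel_profile(flags: pd.DataFrame, cls: str, utc_offset_h: float = -10.0) -> pd.DataFrame:
    """Hour-of-day activity profile in local time.

    Buckets each minute file by local hour (``utc_offset_h`` hours from
    UTC; Hawai'i standard time is -10, no DST) and reports, per hour,
    the observation minutes, positive minutes and their percentage.
    """
    hours = _local_hour(flags["start_utc"], utc_offset_h)
    out = []
    for h in range(24):
        sel = flags[hours == h]
        n = len(sel)
        pos = int(sel[cls].sum()) if n else 0
        out.append(
            {
                "hour": h,
                "observation_minutes": n,
                "positive_minutes": pos,
                "percentage": 100.0 * pos / n if n else math.nan,
            }
        )
    return pd.DataFrame(out)


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from the sum-of-squares definitions.

    Returns ``(F, p)``; ``(nan, nan)`` for degenerate input (fewer than
    2 groups, any group with < 2 observations counted toward residual
    df <= 0, or zero within-group variance with zero between-group
    variance).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    if k < 2 or n - k < 1:
        return math.nan, math.nan
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        if ms_between == 0.0:
            return math.nan, math.nan
        return math.inf, 0.0
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def day_night_anova(
    flags: pd.DataFrame,
    cls: str,
    utc_offset_h: float = -10.0,
    day_hours: Sequence[int] = DAY_HOURS,
    night_hours: Sequence[int] = NIGHT_HOURS,
) -> dict:
    """Day vs night one-way ANOVA on per-dive-hour positive percentages.

    Observations are the percentage of positive minute files within each
    (dive, local hour) cell — one value per dive-hour of recording —
    split into day and night groups.  The group boundary (day
    07:00-18:00, night 19:00-06:00 local) is configuration and is echoed
    in the result.
    """
    df = flags.copy()
    df["hour"] = _local_hour(df["start_utc"], utc_offset_h)
    cell = (
        df.groupby(["dive_id", "hour"])[cls]
        .agg(["sum", "size"])
        .reset_index()
    )
    cell["pct"] = 100.0 * cell["sum"] / cell["size"]
    day = cell.loc[cell["hour"].isin(day_hours), "pct"].to_numpy()
    night = cell.loc[cell["hour"].isin(night_hours), "pct"].to_numpy()
    f, p = one_way_anova([day, night])
    return {
        "F": f,
        "p": p,
        "day_mean_pct": float(day.mean()) if len(day) else math.nan,
        "night_mean_pct": float(night.mean()) if len(night) else math.nan,
        "n_day": int(len(day)),
        "n_night": int(len(night)),
        "day_hours": tuple(day_hours),
        "night_hours": tuple(night_hours),
    }


@dataclass
class Encounter:
    """A maximal run of positive files for one class."""

    cls: str
    dive_ids: list
    start_utc: pd.Timestamp
    end_utc: pd.Timestamp
    n_files: int


def count_encounters(
    flags: pd.DataFrame, cls: str, max_gap_s: float = 3600.0
) -> list[Encounter]:
    """Group positive files into acoustic encounters.

    Positive files whose start times differ by at most ``max_gap_s``
    (default one hour, i.e. gaps within one dive) belong to one
    encounter.  ``flags`` must be time-sorted.
    """
    pos = flags.loc[flags[cls]].copy()
    if len(pos) == 0:
        return []
    times = pd.to_datetime(pos["start_utc"]).reset_index(drop=True)
    if not times.is_monotonic_increasing:
        raise ValueError("flags must be sorted by start_utc")
    encounters = []
    start = 0
    t = times.to_numpy()
    for i in range(1, len(pos) + 1):
        if i == len(pos) or (t[i] - t[i - 1]) / np.timedelta64(1, "s") > max_gap_s:
            chunk = pos.iloc[start:i]
            encounters.append(
                Encounter(
                    cls=cls,
                    dive_ids=sorted(chunk["dive_id"].unique().tolist())
                    if "dive_id" in chunk
                    else [],
                    start_utc=times[start],
                    end_utc=times[i - 1],
                    n_files=len(chunk),
                )
            )
            start = i
    return encounters


def encounter_rate(total_recording_h: float, n_encounters: int) -> float:
    """Recording hours per acoustic encounter (inf for zero encounters)."""
    if n_encounters == 0:
        return math.inf
    return total_recording_h / n_encounters


def detector_performance(
    truth_flags: pd.Series,
    detector_flags: pd.Series,
    dive_of_file: Optional[pd.Series] = None,
) -> dict:
    """File-level recall and dive-level true/false detection counts.

    All three series are indexed by file_id over the same universe.
    ``file_recall_pct`` is 100 x (files truth-positive and detected) /
    (files truth-positive).  With a dive index, a dive counts as a true
    detection when the detector fires on a dive holding any truth
    positive, and a false detection when it fires on a dive with none.

    Raises
    ------
    ValueError
        If the file universes differ.
    """
    if not truth_flags.index.equals(detector_flags.index):
        raise ValueError("truth and detector flags cover different file sets")
    tp_files = int((truth_flags & detector_flags).sum())
    pos_files = int(truth_flags.sum())
    out = {
        "truth_positive_files": pos_files,
        "detected_true_files": tp_files,
        "file_recall_pct": 100.0 * tp_files / pos_files if pos_files else math.nan,
    }
    if dive_of_file is not None:
        if not truth_flags.index.equals(dive_of_file.index):
            raise ValueError("dive index covers a different file set")
        per_dive = pd.DataFrame(
            {"truth": truth_flags, "det": detector_flags, "dive": dive_of_file}
        ).groupby("dive")[["truth", "det"]].any()
        out["dive_detections"] = int(per_dive["det"].sum())
        out["dive_true_detections"] = int((per_dive["det"] & per_dive["truth"]).sum())
        out["dive_false_detections"] = int((per_dive["det"] & ~per_dive["truth"]).sum())
    return out


def write_report(
    flags: pd.DataFrame,
    out_dir: str | Path,
    classes: Optional[Sequence[str]] = None,
    utc_offset_h: float = -10.0,
) -> dict:
    """Write mission report (CSV + JSON + per-dive GeoJSON) and return it.

    Percentages are rounded to 1 decimal in the JSON report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classes = list(classes) if classes is not None else [
        c for c in flags.columns if flags[c].dtype == bool
    ]
    report = {
        "n_files": int(len(flags)),
        "n_dives": int(flags["dive_id"].nunique()) if "dive_id" in flags else None,
        "percent_by_class": {
            c: round(percent_with_class(flags, c), 1) for c in classes
        },
    }
    dives = dive_summaries(flags, classes)
    dives.to_csv(out / "dive_summaries.csv", index=False)
    for c in classes:
        diel_profile(flags, c, utc_offset_h).to_csv(
            out / f"diel_{c}.csv", index=False
        )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    if {"mean_lat", "mean_lon"} <= set(dives.columns):
        feats = []
        for _, row in dives.iterrows():
            props = {"dive_id": int(row["dive_id"])}
            props.update({f"{c}_pct": row[f"{c}_pct"] for c in classes})
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [row["mean_lon"], row["mean_lat"]],
                    },
                    "properties": props,
                }
            )
        with open(out / "dives.geojson", "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    return report
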