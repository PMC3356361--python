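"""Rule-based species classification of click trains.

The rules encode how an analyst separates the recorded click classes:

* **Beaked whales** (ziphiids): FM upsweep, a -20 dB low-frequency
  roll-off at or above ~20 kHz, and species-specific duration/ICI
  windows.  Blainville's beaked whale: ~250 us clicks, roll-off
  ~25 kHz, ICI 0.2-0.4 s.  Cuvier's beaked whale: ~175 us, roll-off
  ~20 kHz, ICI ~0.4 s.  Trains that carry the beaked-whale signature
  (upsweep + high roll-off + beaked-scale duration) but match no
  species window are labelled ``unidentified_beaked_whale`` — for
  example an 11-click train with 530 us clicks and 0.12 s ICI, far
  shorter than either known species' interval.
* **Sperm whales**: long, low-frequency clicks (spectral peak below
  20 kHz) with slow, regular ICIs of 0.5-1 s.
* **Delphinids**: very short (<~120 us) broadband clicks without a
  consistent upsweep and with irregular, fast ICIs.
* **Echosounders**: metronomic narrowband pings — near-zero ICI
  variability and a tone-like spectrum.

Point values become acceptance windows via configurable tolerance
fractions (default +/-30 % on duration and roll-off); the windows and
precedence are explicit configuration, not facts — analyst judgement is
irreducibly informal.  When both beaked-whale windows accept a train,
the nearest window in normalised (duration, roll-off, ICI) space wins.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from .features import ClickTrain

__all__ = ["SpeciesWindow", "RuleSet", "classify_train", "flag_files", "CLASS_COLUMNS"]

CLASS_COLUMNS = ["beaked_whale", "delphinid", "sperm_whale", "echosounder"]

#: train label -> per-file class column
LABEL_TO_CLASS = {
    "blainville": "beaked_whale",
    "cuvier": "beaked_whale",
    "unidentified_beaked_whale": "beaked_whale",
    "delphinid": "delphinid",
    "sperm_whale": "sperm_whale",
    "echosounder": "echosounder",
}


@dataclass(frozen=True)
class SpeciesWindow:
    """Acceptance window for one beaked-whale species."""

    duration_us: float
    lf_rolloff_hz: float
    ici_s_range: tuple[float, float]

    def ici_center(self) -> float:
        return 0.5 * (self.ici_s_range[0] + self.ici_s_range[1])


@dataclass(frozen=True)
class RuleSet:
    """Explicit, serialisable classification rules (see module docstring)."""

    blainville: SpeciesWindow = field(
        default_factory=lambda: SpeciesWindow(250.0, 25_000.0, (0.2, 0.4))
    )
    cuvier: SpeciesWindow = field(
        default_factory=lambda: SpeciesWindow(175.0, 20_000.0, (0.3, 0.5))
    )
    precedence: tuple[str, ...] = ("blainville", "cuvier")
    duration_tol_frac: float = 0.30
    rolloff_tol_frac: float = 0.30
    # beaked-whale signature gate
    beaked_rolloff_min_hz: float = 18_000.0
    beaked_duration_range_us: tuple[float, float] = (100.0, 900.0)
    min_upsweep_slope_khz_per_ms: float = 10.0
    # other classes
    echosounder_max_ici_cv: float = 0.02
    echosounder_min_clicks: int = 4
    echosounder_max_bandwidth_hz: float = 8_000.0
    sperm_max_peak_hz: float = 20_000.0
    sperm_min_ici_s: float = 0.5
    # duration is not gated for sperm whales: the 10 kHz-high-pass duration
    # convention is unreliable for clicks whose energy sits mostly below it
    sperm_min_duration_us: float = 0.0
    delphinid_max_duration_us: float = 120.0
    min_clicks: int = 2

    def __post_init__(self) -> None:
        for name in self.precedence:
            if not isinstance(self.window(name), SpeciesWindow):
                raise ValueError(f"unknown species {name!r} in precedence")
        if len(set(self.precedence)) != len(self.precedence):
            raise ValueError("precedence must list each species exactly once")
        for w in (self.blainville, self.cuvier):
            if w.ici_s_range[0] >= w.ici_s_range[1]:
                raise ValueError("ICI range must be non-empty")

    def window(self, species: str) -> SpeciesWindow:
        return getattr(self, species)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("blainville", "cuvier"):
            if key in raw:
                w = raw[key]
                raw[key] = SpeciesWindow(
                    w["duration_us"], w["lf_rolloff_hz"], tuple(w["ici_s_range"])
                )
        for key in ("precedence", "beaked_duration_range_us"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TrainSummary:
    """The classifier's view of a train (feature medians + ICI stats).

    Constructed from a measured :class:`~gliderpam.features.ClickTrain`
    via :meth:`from_train`, or directly for rule-level tests.
    """

    n_clicks: int
    duration_us: float
    lf_rolloff_hz: float
    ici_mean_s: float
    ici_sd_s: float
    upsweep: Optional[bool]
    upsweep_slope_khz_per_ms: float = math.inf  # "unknown, don't gate on slope"
    peak_freq_hz: float = math.nan
    snr_db: float = math.nan

    @classmethod
    def from_train(cls, train: ClickTrain) -> "TrainSummary":
        dur = train.duration_us
        if not math.isfinite(dur):
            dur = train.duration_us_med
        return cls(
            n_clicks=train.n_clicks,
            duration_us=dur,
            lf_rolloff_hz=train.lf_rolloff_hz,
            ici_mean_s=train.ici_mean_s,
            ici_sd_s=train.ici_sd_s,
            upsweep=train.upsweep,
            upsweep_slope_khz_per_ms=train.upsweep_slope_med,
            peak_freq_hz=train.peak_freq_hz,
            snr_db=train.snr_db_med,
        )


def _in_window(value: float, center: float, tol_frac: float) -> bool:
    return abs(value - center) <= tol_frac * center


def _window_distance(ts: TrainSummary, w: SpeciesWindow) -> float:
    """Normalised distance of a train to a species window centre."""
    d = abs(ts.duration_us - w.duration_us) / w.duration_us
    r = 0.0
    if math.isfinite(ts.lf_rolloff_hz):
        r = abs(ts.lf_rolloff_hz - w.lf_rolloff_hz) / w.lf_rolloff_hz
    i = abs(ts.ici_mean_s - w.ici_center()) / w.ici_center()
    return math.hypot(d, math.hypot(r, i))


def classify_train(
    summary: TrainSummary | ClickTrain, rules: RuleSet = RuleSet()
) -> tuple[str, list[str]]:
    """Assign a species label to one click train.

    Returns ``(label, trace)`` where ``trace`` records the rule path
    taken.  Labels: ``blainville``, ``cuvier``,
    ``unidentified_beaked_whale``, ``delphinid``, ``sperm_whale``,
    ``echosounder``, ``unknown``.
    """
    ts = TrainSummary.from_train(summary) if isinstance(summary, ClickTrain) else summary
    trace: list[str] = []

    if ts.n_clicks < rules.min_clicks or not math.isfinite(ts.duration_us):
        trace.append("missing or insufficient features")
        return "unknown", trace
    if not math.isfinite(ts.ici_mean_s):
        trace.append("no ICI series")
        return "unknown", trace

    # 1. echosounder: metronomic narrowband pings
    cv = ts.ici_sd_s / ts.ici_mean_s if ts.ici_mean_s > 0 else math.inf
    narrowband = (
        math.isfinite(ts.lf_rolloff_hz)
        and math.isfinite(ts.peak_freq_hz)
        and (ts.peak_freq_hz - ts.lf_rolloff_hz) <= rules.echosounder_max_bandwidth_hz
    )
    if (
        ts.n_clicks >= rules.echosounder_min_clicks
        and cv <= rules.echosounder_max_ici_cv
        and narrowband
    ):
        trace.append(f"metronomic (ICI CV {cv:.3f}) narrowband pings -> echosounder")
        return "echosounder", trace

    # 2. beaked-whale signature gate
    slope_ok = (
        not math.isfinite(ts.upsweep_slope_khz_per_ms)
        or ts.upsweep_slope_khz_per_ms >= rules.min_upsweep_slope_khz_per_ms
    )
    lo_d, hi_d = rules.beaked_duration_range_us
    if (
        ts.upsweep is True
        and slope_ok
        and math.isfinite(ts.lf_rolloff_hz)
        and ts.lf_rolloff_hz >= rules.beaked_rolloff_min_hz
        and lo_d <= ts.duration_us <= hi_d
    ):
        trace.append("upsweep + high roll-off + beaked-scale duration: beaked whale")
        candidates = []
        for name in rules.precedence:
            w = rules.window(name)
            dur_ok = _in_window(ts.duration_us, w.duration_us, rules.duration_tol_frac)
            roll_ok = not math.isfinite(ts.lf_rolloff_hz) or _in_window(
                ts.lf_rolloff_hz, w.lf_rolloff_hz, rules.rolloff_tol_frac
            )
            ici_ok = w.ici_s_range[0] <= ts.ici_mean_s <= w.ici_s_range[1]
            if dur_ok and roll_ok and ici_ok:
                candidates.append(name)
        if len(candidates) == 1:
            trace.append(f"matches {candidates[0]} window")
            return candidates[0], trace
        if len(candidates) > 1:
            best = min(candidates, key=lambda n: _window_distance(ts, rules.window(n)))
            trace.append(
                f"multiple windows {candidates}; nearest in feature space: {best}"
            )
            return best, trace
        trace.append("no species window matches -> unidentified beaked whale")
        return "unidentified_beaked_whale", trace

    # 3. sperm whale: long low-frequency clicks, slow regular ICI
    if (
        math.isfinite(ts.peak_freq_hz)
        and ts.peak_freq_hz <= rules.sperm_max_peak_hz
        and ts.ici_mean_s >= rules.sperm_min_ici_s
        and ts.duration_us >= rules.sperm_min_duration_us
    ):
        trace.append("low-frequency long clicks with ICI >= 0.5 s -> sperm whale")
        return "sperm_whale", trace

    # 4. delphinid: very short broadband clicks, no upsweep
    if ts.duration_us <= rules.delphinid_max_duration_us and ts.upsweep is not True:
        trace.append("short broadband non-upsweep clicks -> delphinid")
        return "delphinid", trace

    trace.append("no rule matched")
    return "unknown", trace


def flag_files(
    labelled_trains: pd.DataFrame, file_index: Sequence[str]
) -> pd.DataFrame:
    """Roll train labels up to per-minute-file presence flags.

    ``labelled_trains`` needs columns ``file_id`` and ``label``.  The
    result has one row per file in ``file_index`` with boolean columns
    for each class plus ``beaked_detail`` (``blainville``, ``cuvier``,
    ``unidentified`` or ``""``); a file may carry several class flags.

    Raises
    ------
    KeyError
        If a train references a file outside ``file_index``.
    """
    idx = pd.Index(file_index, name="file_id")
    flags = pd.DataFrame(False, index=idx, columns=CLASS_COLUMNS)
    flags["beaked_detail"] = ""
    detail_rank = {"blainville": 2, "cuvier": 2, "unidentified": 1, "": 0}
    for _, row in labelled_trains.iterrows():
        fid, label = row["file_id"], row["label"]
        if fid not in idx:
            raise KeyError(f"train references unknown file {fid!r}")
        cls = LABEL_TO_CLASS.get(label)
        if cls is None:
            continue
        flags.loc[fid, cls] = True
        if cls == "beaked_whale":
            detail = "unidentified" if label == "unidentified_beaked_whale" else label
            if detail_rank[detail] > detail_rank[flags.loc[fid, "beaked_detail"]]:
                flags.loc[fid, "beaked_detail"] = detail
    return flags
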