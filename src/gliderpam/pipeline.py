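"""End-to-end wiring: audio -> detections -> trains -> labels -> flags.

Convenience drivers shared by the CLI, the tests and the acceptance
script.  Each stage stays individually accessible through its own
module; these functions only connect them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .audio import parse_filename, read_wav
from .classify import RuleSet, TrainSummary, classify_train, flag_files
from .detect import DetectorConfig, SpectrogramConfig, detect_clicks, group_into_trains
from .features import FeatureConfig, measure_train

__all__ = ["PipelineConfig", "process_samples", "process_file", "process_mission"]


@dataclass
class PipelineConfig:
    """Configuration bundle for the full analysis chain."""

    sample_rate_hz: float = 194_000.0
    spectrogram: Optional[SpectrogramConfig] = None
    detector: DetectorConfig = field(default_factory=DetectorConfig.analyst)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    rules: RuleSet = field(default_factory=RuleSet)

    def spec_cfg(self, fs: float) -> SpectrogramConfig:
        if self.spectrogram is not None:
            return self.spectrogram
        return SpectrogramConfig.detection(fs)


def _spectral_cells(train) -> dict[str, list]:
    """Partition a train's events by per-click spectral character.

    Clicks from different sources recorded simultaneously (e.g. a
    delphinid train over echosounder pings) end up gap-grouped into one
    train; splitting by coarse per-click spectral class (low-frequency /
    narrowband / broadband) lets each component be classified on its
    own.
    """
    cells: dict[str, list] = {}
    for ev, f in zip(train.events, train.features):
        if np.isfinite(f.peak_freq_hz) and f.peak_freq_hz < 20_000.0:
            key = "low"
        elif (
            np.isfinite(f.peak_freq_hz)
            and np.isfinite(f.lf_rolloff_hz)
            and f.peak_freq_hz - f.lf_rolloff_hz <= 8_000.0
        ):
            key = "narrow"
        else:
            key = "broad"
        cells.setdefault(key, []).append(ev)
    return cells


def process_samples(
    samples: np.ndarray,
    fs: float,
    cfg: PipelineConfig,
    file_id: str = "",
    file_start_utc: Optional[datetime] = None,
) -> tuple[list, pd.DataFrame]:
    """Run detect -> group -> measure -> classify on one recording.

    Returns ``(events, trains)`` where ``trains`` has one row per
    classified click train (or spectrally split sub-train) with its
    summary features and label.
    """
    events = detect_clicks(
        samples, cfg.spec_cfg(fs), cfg.detector, file_id=file_id,
        file_start_utc=file_start_utc,
    )
    rows = []
    for group in group_into_trains(events, cfg.detector):
        train = measure_train(group, cfg.features)
        label, trace = classify_train(TrainSummary.from_train(train), cfg.rules)
        row = {"file_id": file_id, "label": label, **train.summary()}
        row["start_s"] = group[0].onset_s
        row["trace"] = " | ".join(trace)
        rows.append(row)
        # mixed-source trains: classify spectral sub-trains as well
        cells = _spectral_cells(train)
        big = [c for c in cells.values() if len(c) >= cfg.detector.min_clicks_per_train]
        if len(cells) > 1 and big and max(len(c) for c in cells.values()) < train.n_clicks:
            seen = {label}
            for cell in big:
                sub = measure_train(cell, cfg.features)
                sub_label, sub_trace = classify_train(
                    TrainSummary.from_train(sub), cfg.rules
                )
                if sub_label in seen or sub_label == "unknown":
                    continue
                seen.add(sub_label)
                sub_row = {"file_id": file_id, "label": sub_label, **sub.summary()}
                sub_row["start_s"] = cell[0].onset_s
                sub_row["trace"] = "sub-train | " + " | ".join(sub_trace)
                rows.append(sub_row)
    trains = pd.DataFrame(rows)
    return events, trains


def process_file(path: str | Path, cfg: PipelineConfig) -> tuple[list, pd.DataFrame]:
    """Detect and classify clicks in one WAV minute file."""
    path = Path(path)
    samples, fs = read_wav(path)
    try:
        meta = parse_filename(path.name)
        start = meta["start_utc"]
    except ValueError:
        start = None
    return process_samples(samples, fs, cfg, file_id=path.stem, file_start_utc=start)


def process_mission(
    files: Iterable, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process an iterable of minute files into train and flag tables.

    ``files`` yields either WAV paths or ``(meta, samples)`` /
    ``(meta, samples, truth)`` tuples as produced by
    :func:`gliderpam.synth.iter_mission`.  Returns ``(trains, flags)``
    where ``flags`` has one row per file with class booleans plus
    ``dive_id`` and ``start_utc`` when known.
    """
    all_trains = []
    file_rows = []
    for item in files:
        if isinstance(item, (str, Path)):
            path = Path(item)
            samples, fs = read_wav(path)
            fid = path.stem
            try:
                info = parse_filename(path.name)
                dive, start = info["dive_id"], info["start_utc"]
            except ValueError:
                dive, start = None, None
        else:
            meta, samples = item[0], item[1]
            fid, fs = meta.file_id, meta.sample_rate_hz
            dive, start = meta.dive_id, meta.start_utc
        _, trains = process_samples(samples, fs, cfg, file_id=fid, file_start_utc=start)
        all_trains.append(trains)
        file_rows.append({"file_id": fid, "dive_id": dive, "start_utc": start})
    trains = (
        pd.concat([t for t in all_trains if len(t)], ignore_index=True)
        if any(len(t) for t in all_trains)
        else pd.DataFrame(columns=["file_id", "label"])
    )
    files_df = pd.DataFrame(file_rows)
    flags = flag_files(trains, files_df["file_id"].tolist()) if len(files_df) else pd.DataFrame()
    flags = files_df.merge(flags.reset_index(), on="file_id", how="left")
    bool_cols = [c for c in ("beaked_whale", "delphinid", "sperm_whale", "echosounder") if c in flags]
    flags[bool_cols] = flags[bool_cols].fillna(False).astype(bool)
    flags["beaked_detail"] = flags.get("beaked_detail", "").fillna("")
    return trains, flags
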