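"""Echolocation-click detection by spectrogram band-energy ratios.

The detector frames a (high-pass-filtered) recording into short Hamming
windows, computes per-frame band power, and flags frames whose power
ratio exceeds a threshold.  Two ratio modes are provided:

``band``
    The low-power onboard-screening scheme: mean power in a
    beaked-whale signal band over mean power in a low-frequency guard
    band (an energy-ratio detector).  Beaked-whale clicks concentrate
    energy at 25-50 kHz with none below ~20 kHz, so they score high
    while sperm-whale clicks and most vessel noise do not.
``baseline``
    An analyst-style broadband transient detector used by the full
    pipeline: each frame's mean power in several sub-bands is compared
    with that sub-band's median over the whole file (the noise floor),
    and the maximum sub-band ratio is taken.  This detects delphinid,
    sperm-whale and echosounder transients as well.

Contiguous above-threshold frames form one candidate click; the event
onset is the centre time of the run's peak-ratio frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "SpectrogramConfig",
    "DetectorConfig",
    "ClickEvent",
    "spectrogram",
    "band_energy_ratio",
    "detect_clicks",
    "group_into_trains",
]


@dataclass(frozen=True)
class SpectrogramConfig:
    """Framing parameters for spectrogram analysis.

    The two analyst configurations used for screening and for resolving
    click FM contours are available via :meth:`analyst_screen` and
    :meth:`click_fine`; :meth:`detection` is the transient-detection
    framing (frame shorter than a click train's ICI but comparable to a
    click, 75 % overlap for alignment).
    """

    sample_rate_hz: float
    frame_size: int = 2048
    fft_size: int = 2048
    overlap: float = 0.5
    window: str = "hamming"
    highpass_hz: Optional[float] = 5_000.0

    def __post_init__(self) -> None:
        if self.fft_size < self.frame_size:
            raise ValueError("fft_size must be >= frame_size")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.highpass_hz is not None and self.highpass_hz >= self.sample_rate_hz / 2:
            raise ValueError("highpass_hz must be below Nyquist")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.frame_size * (1.0 - self.overlap))))

    @property
    def reported_bandwidth_hz(self) -> float:
        """Hamming main-lobe (null-to-null) bandwidth, 4 fs / frame.

        Display bandwidths quoted for analyst software vary by
        convention; the main-lobe width is used here because it scales
        exactly with the inverse frame size, so the 2048- and 32-sample
        configurations differ by exactly their frame-size ratio.
        """
        return 4.0 * self.sample_rate_hz / self.frame_size

    @classmethod
    def analyst_screen(cls, sample_rate_hz: float = 194_000.0) -> "SpectrogramConfig":
        """2048-sample frames (11 ms), 50 % overlap: file screening."""
        return cls(sample_rate_hz, 2048, 2048, 0.5, "hamming", 5_000.0)

    @classmethod
    def click_fine(cls, sample_rate_hz: float = 194_000.0) -> "SpectrogramConfig":
        """32-sample frames (0.16 ms), 128-point FFT, 94 % overlap:
        resolves the upsweep contour within a single click."""
        return cls(sample_rate_hz, 32, 128, 0.9375, "hamming", 10_000.0)

    @classmethod
    def detection(cls, sample_rate_hz: float = 194_000.0) -> "SpectrogramConfig":
        """128-sample frames, 75 % overlap: transient detection."""
        return cls(sample_rate_hz, 128, 256, 0.75, "hamming", 5_000.0)


@dataclass(frozen=True)
class DetectorConfig:
    """Band/threshold configuration for the click detector.

    In ``band`` mode the statistic is mean signal-band power over mean
    guard-band power; the default bands and 10 dB threshold make
    beaked-whale clicks (roll-off 20-25 kHz, upsweep into 30-50 kHz)
    score high while low-frequency sperm-whale energy does not.  In
    ``baseline`` mode the statistic is the maximum over ``sub_bands`` of
    frame power relative to that band's file-median power.
    """

    signal_band_hz: tuple[float, float] = (24_000.0, 48_000.0)
    guard_band_hz: tuple[float, float] = (5_000.0, 20_000.0)
    ratio_threshold_db: float = 10.0
    min_gap_s: float = 0.003
    min_clicks_per_train: int = 5
    max_ici_s: float = 2.0
    mode: str = "band"
    # sub-bands are kept >= ~13 FFT bins wide so the per-frame mean-power
    # ratio is chi-square-concentrated and the false-alarm rate at the
    # default threshold stays negligible
    sub_bands_hz: tuple[tuple[float, float], ...] = (
        (10_000.0, 20_000.0),
        (20_000.0, 40_000.0),
        (40_000.0, 92_000.0),
    )

    def __post_init__(self) -> None:
        if self.mode not in ("band", "baseline"):
            raise ValueError("mode must be 'band' or 'baseline'")
        lo_s, hi_s = self.signal_band_hz
        lo_g, hi_g = self.guard_band_hz
        if not (lo_s < hi_s and lo_g < hi_g):
            raise ValueError("bands must be (low, high) with low < high")
        if self.mode == "band" and not (hi_g <= lo_s or hi_s <= lo_g):
            raise ValueError("signal and guard bands must be disjoint")
        if not math.isfinite(self.ratio_threshold_db):
            raise ValueError("ratio_threshold_db must be finite")
        if self.min_clicks_per_train < 1:
            raise ValueError("min_clicks_per_train must be >= 1")

    @classmethod
    def erma(cls) -> "DetectorConfig":
        """Onboard-screening defaults (band-energy-ratio, 10 dB)."""
        return cls()

    @classmethod
    def analyst(cls) -> "DetectorConfig":
        """Broadband pipeline defaults (baseline mode, 4.5 dB)."""
        return cls(mode="baseline", ratio_threshold_db=4.5)


@dataclass
class ClickEvent:
    """One detected transient with its local waveform window.

    ``onset_s`` is seconds from file start (0-based); ``absolute_time``
    is the file timestamp plus onset when a timestamp is known.
    ``window`` holds raw samples around the click starting at
    ``window_start_s``.
    """

    file_id: str
    onset_s: float
    ratio_db: float
    window: np.ndarray
    window_start_s: float
    sample_rate_hz: float
    absolute_time: Optional[datetime] = None


def spectrogram(
    samples: np.ndarray, cfg: SpectrogramConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude spectrogram: returns ``(freqs_hz, times_s, mag)``.

    Frames of ``cfg.frame_size`` samples advance by
    ``frame_size * (1 - overlap)``; the column count for N samples is
    ``floor((N - frame) / hop) + 1``.  Times are frame centres.

    Raises
    ------
    ValueError
        For input shorter than one frame.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < cfg.frame_size:
        raise ValueError(
            f"input of {x.size} samples is shorter than one frame "
            f"({cfg.frame_size} samples)"
        )
    win = signal.get_window(cfg.window, cfg.frame_size, fftbins=True)
    f, t, sx = signal.spectrogram(
        x,
        fs=cfg.sample_rate_hz,
        window=win,
        nperseg=cfg.frame_size,
        noverlap=cfg.frame_size - cfg.hop,
        nfft=cfg.fft_size,
        detrend=False,
        mode="magnitude",
        scaling="spectrum",
    )
    return f, t, sx


def band_energy_ratio(
    spectrum_column: np.ndarray, freqs_hz: np.ndarray, cfg: DetectorConfig
) -> float:
    """10 log10 of mean signal-band power over mean guard-band power.

    ``spectrum_column`` is a magnitude (or power) column; magnitudes are
    squared to power internally if non-negative amplitudes are passed.
    Returns ``+inf`` when the guard band holds exactly zero power.
    """
    col = np.asarray(spectrum_column, dtype=float)
    power = col**2
    nyq = freqs_hz[-1]
    for lo, hi in (cfg.signal_band_hz, cfg.guard_band_hz):
        if hi > nyq * 1.0001:
            raise ValueError(f"band ({lo:g}, {hi:g}) Hz exceeds Nyquist {nyq:g} Hz")
    sig = power[(freqs_hz >= cfg.signal_band_hz[0]) & (freqs_hz < cfg.signal_band_hz[1])]
    guard = power[(freqs_hz >= cfg.guard_band_hz[0]) & (freqs_hz < cfg.guard_band_hz[1])]
    g = guard.mean()
    s = sig.mean()
    if g == 0.0:
        return math.inf
    return 10.0 * math.log10(s / g) if s > 0 else -math.inf


def _column_ratios_db(
    power: np.ndarray, freqs: np.ndarray, det_cfg: DetectorConfig
) -> np.ndarray:
    if det_cfg.mode == "band":
        sig = power[(freqs >= det_cfg.signal_band_hz[0]) & (freqs < det_cfg.signal_band_hz[1])]
        guard = power[(freqs >= det_cfg.guard_band_hz[0]) & (freqs < det_cfg.guard_band_hz[1])]
        s = sig.mean(axis=0)
        g = guard.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(g > 0, s / np.where(g > 0, g, 1.0), np.inf)
            return 10.0 * np.log10(np.maximum(r, 1e-300))
    best = np.full(power.shape[1], -np.inf)
    for lo, hi in det_cfg.sub_bands_hz:
        rows = (freqs >= lo) & (freqs < hi)
        if not rows.any():
            continue
        p = power[rows].mean(axis=0)
        floor = np.median(p)
        if floor <= 0:
            floor = np.mean(p) or 1e-300
        np.maximum(best, p / floor, out=best)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(np.maximum(best, 1e-300))


def detect_clicks(
    samples: np.ndarray,
    spec_cfg: SpectrogramConfig,
    det_cfg: DetectorConfig,
    file_id: str = "",
    file_start_utc: Optional[datetime] = None,
    window_pre_s: float = 0.008,
    window_post_s: float = 0.004,
) -> list[ClickEvent]:
    """Detect click transients in one recording.

    Returns time-ordered :class:`ClickEvent` objects, one per contiguous
    run of above-threshold frames, with events closer than
    ``det_cfg.min_gap_s`` merged (keeping the stronger).
    """
    fs = spec_cfg.sample_rate_hz
    x = np.asarray(samples, dtype=float)
    if spec_cfg.highpass_hz:
        sos = signal.butter(4, spec_cfg.highpass_hz, "highpass", fs=fs, output="sos")
        xf = signal.sosfiltfilt(sos, x)
    else:
        xf = x
    freqs, times, mag = spectrogram(xf, spec_cfg)
    ratios = _column_ratios_db(mag, freqs, det_cfg)

    above = ratios >= det_cfg.ratio_threshold_db
    events: list[ClickEvent] = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        k = i + int(np.argmax(ratios[i : j + 1]))
        events.append(
            ClickEvent(
                file_id=file_id,
                onset_s=float(times[k]),
                ratio_db=float(ratios[k]),
                window=np.empty(0),
                window_start_s=0.0,
                sample_rate_hz=fs,
            )
        )
        i = j + 1

    # merge events closer than min_gap_s, keeping the stronger
    merged: list[ClickEvent] = []
    for ev in events:
        if merged and ev.onset_s - merged[-1].onset_s < det_cfg.min_gap_s:
            if ev.ratio_db > merged[-1].ratio_db:
                merged[-1] = ev
            continue
        merged.append(ev)

    for ev in merged:
        i0 = max(0, int(round((ev.onset_s - window_pre_s) * fs)))
        i1 = min(len(x), int(round((ev.onset_s + window_post_s) * fs)))
        ev.window = x[i0:i1].copy()
        ev.window_start_s = i0 / fs
        if file_start_utc is not None:
            ev.absolute_time = file_start_utc + timedelta(seconds=ev.onset_s)
    return merged


def group_into_trains(
    events: Sequence[ClickEvent], det_cfg: DetectorConfig
) -> list[list[ClickEvent]]:
    """Group time-sorted events into click trains.

    Consecutive events with onset gaps <= ``max_ici_s`` belong to one
    train; trains with fewer than ``min_clicks_per_train`` events are
    discarded.
    """
    trains: list[list[ClickEvent]] = []
    current: list[ClickEvent] = []
    for ev in events:
        if current and ev.onset_s - current[-1].onset_s > det_cfg.max_ici_s:
            if len(current) >= det_cfg.min_clicks_per_train:
                trains.append(current)
            current = []
        current.append(ev)
    if len(current) >= det_cfg.min_clicks_per_train:
        trains.append(current)
    return trains
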