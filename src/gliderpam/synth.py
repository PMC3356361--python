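"""Synthetic click, click-train, mission, and track generation.

Every downstream stage of the pipeline (detection, feature measurement,
classification, mission statistics, tag matching) is exercised on data
from this module, so the generator is calibrated rather than merely
plausible: a click synthesised from a :class:`~gliderpam.presets.ClickSpec`
is iteratively shaped until its *measured* 95 %-energy duration, spectral
peak and -20 dB low-frequency roll-off match the spec, and train
amplitudes are scaled against the actual noise realisation so the
measured band-limited SNR_0-p hits the target.

Waveform model
--------------
A click is a linear FM chirp under an asymmetric Gaussian envelope.  The
rising side of the envelope is set so the spectrum first comes within
20 dB of its peak near the spec's roll-off frequency; the envelope peak
is placed where the instantaneous frequency equals the spec's peak
frequency (by stationary phase the spectral maximum of a linear chirp
tracks the envelope maximum).  Zero-phase Butterworth confinement
filters remove out-of-band leakage so the spectrum is strongly band
limited.  No propagation effects beyond a scalar SNR are modelled.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .features import energy_duration_s
from .presets import PRESETS, ClickSpec, NoiseModel, get_preset

__all__ = [
    "make_noise",
    "make_click_waveform",
    "make_click_train",
    "TrainTruth",
    "MissionScenario",
    "FileMeta",
    "iter_mission",
    "make_mission",
    "truth_flags",
    "make_tag_track",
    "make_glider_track",
]

_SQRT2LN10 = math.sqrt(2.0 * math.log(10.0))  # amplitude is -20 dB at this many sigma
_SNR_BAND_HZ = (15_000.0, 90_000.0)  # SNR_0-p convention band


# ---------------------------------------------------------------------------
# noise

def make_noise(n: int, fs: float, model: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with ``model.rms`` and an optional spectral tilt."""
    x = rng.standard_normal(n)
    if model.slope_db_per_octave != 0.0:
        X = np.fft.rfft(x)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        ref = fs / 8.0
        with np.errstate(divide="ignore"):
            octaves = np.log2(np.maximum(f, 1.0) / ref)
        X *= 10.0 ** (model.slope_db_per_octave * octaves / 20.0)
        x = np.fft.irfft(X, n)
    r = np.sqrt(np.mean(x * x))
    if r > 0:
        x *= model.rms / r
    return x


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo = max(band[0], 10.0)
    hi = min(band[1], 0.985 * fs / 2)
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def band_rms(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """RMS of ``x`` band-pass filtered to ``band`` (zero-phase)."""
    y = signal.sosfiltfilt(_bandpass_sos(band, fs), x)
    return float(np.sqrt(np.mean(y * y)))


def snr_calibration_band(spec: ClickSpec) -> tuple[float, float]:
    """Band used to calibrate SNR_0-p for a click type.

    The convention band is 15-90 kHz; click types whose energy lies
    mostly below it (sperm-whale pulses) are calibrated in their own
    band instead, since the convention band would contain almost no
    click energy.
    """
    lo, hi = spec.band_hz
    olo, ohi = max(lo, _SNR_BAND_HZ[0]), min(hi, _SNR_BAND_HZ[1])
    overlap = max(0.0, ohi - olo)
    if overlap >= 0.5 * (hi - lo):
        return _SNR_BAND_HZ
    return (max(lo - 2_000.0, 1_000.0), hi + 5_000.0)


# ---------------------------------------------------------------------------
# single-click synthesis

def _envelope(t: np.ndarray, t_peak: float, sig_r: float, sig_f: float) -> np.ndarray:
    e = np.empty_like(t)
    rise = t < t_peak
    e[rise] = np.exp(-0.5 * ((t[rise] - t_peak) / sig_r) ** 2)
    e[~rise] = np.exp(-0.5 * ((t[~rise] - t_peak) / sig_f) ** 2)
    return e


def _synth_core(
    spec: ClickSpec,
    fs: float,
    T: float,
    peak_frac: float,
    roll_hz: Optional[float] = None,
    margin_s: float = 0.0015,
) -> np.ndarray:
    """Synthesise one (unit-peak) click: chirp * envelope + confinement filters."""
    n = max(int(round(T * fs)), 4)
    t = np.arange(n) / fs
    f0, f1 = spec.f_start_hz, spec.f_end_hz
    k = (f1 - f0) / T
    phase = 2.0 * np.pi * (f0 * t + 0.5 * k * t * t)

    span = f1 - f0
    t_peak = peak_frac * T
    if roll_hz is None:
        roll_hz = spec.lf_rolloff_hz
    if roll_hz is not None and span != 0.0:
        t_roll = (roll_hz - f0) / span * T
        # A rise shorter than ~sqrt(1/(2 pi |k|)) gains no spectral edge
        # sharpness: window smearing then dominates the chirp-rate mapping.
        sig_opt = math.sqrt(1.0 / (2.0 * math.pi * abs(k)))
        sig_r = max((t_peak - t_roll) / _SQRT2LN10, sig_opt, 0.02 * T)
        sig_f = max(0.05 * T, (T - t_peak) / 2.5)
    else:
        sig_r = sig_f = 0.25 * T

    x = _envelope(t, t_peak, sig_r, sig_f) * np.sin(phase)

    m = int(round(margin_s * fs))
    buf = np.zeros(n + 2 * m)
    buf[m:m + n] = x

    lo, hi = spec.band_hz
    hp = max(800.0, lo - 2_000.0)
    lp = min(0.985 * fs / 2.0, hi + 3_000.0)
    buf = signal.sosfiltfilt(signal.butter(8, hp, "highpass", fs=fs, output="sos"), buf)
    buf = signal.sosfiltfilt(signal.butter(8, lp, "lowpass", fs=fs, output="sos"), buf)
    peak = np.abs(buf).max()
    if peak > 0:
        buf = buf / peak
    return buf


def _peak_freq_hz(x: np.ndarray, fs: float, fmin: float = 2_500.0) -> float:
    nfft = max(4096, len(x))
    X = np.abs(np.fft.rfft(x, nfft))
    f = np.fft.rfftfreq(nfft, 1.0 / fs)
    mask = (f >= fmin) & (f <= 0.985 * fs / 2)
    return float(f[mask][np.argmax(X[mask])])


@functools.lru_cache(maxsize=256)
def _calibrated_design(spec: ClickSpec, fs: float) -> tuple[float, float, Optional[float]]:
    """Iteratively solve for (T, peak_frac, roll target) so the measured
    duration, spectral peak and -20 dB roll-off match the spec."""
    from .features import click_spectrum, lf_rolloff

    target_T = spec.duration_us * 1e-6
    span = spec.f_end_hz - spec.f_start_hz
    lo, hi = spec.band_hz
    pk_target = spec.peak_freq_hz
    roll_target = spec.lf_rolloff_hz
    T = target_T * 1.2

    def frac(pk):
        if span == 0.0:
            return 0.5
        return float(np.clip((pk - spec.f_start_hz) / span, 0.08, 0.92))

    for _ in range(8):
        peak_frac = frac(pk_target)
        x = _synth_core(spec, fs, T, peak_frac, roll_target)
        d = energy_duration_s(x, fs)
        if d > 0:
            T *= np.clip(target_T / d, 0.5, 2.0)
        if span != 0.0:
            pk = _peak_freq_hz(x, fs)
            pk_target += 0.7 * (spec.peak_freq_hz - pk)
            pk_target = float(np.clip(pk_target, lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo)))
        if spec.lf_rolloff_hz is not None and span != 0.0:
            f, m = click_spectrum(x, fs)
            meas = lf_rolloff(f, m)
            if math.isfinite(meas):
                roll_target += 0.7 * (spec.lf_rolloff_hz - meas)
                roll_target = float(np.clip(roll_target, lo - 0.2 * (hi - lo), pk_target - 0.02 * (hi - lo)))
    return T, frac(pk_target), roll_target


def make_click_waveform(spec: ClickSpec, sample_rate: float, amplitude: float = 1.0) -> np.ndarray:
    """Synthesise one click at ``sample_rate`` with time-domain peak ``amplitude``.

    The returned buffer includes short silent margins (filter headroom);
    the click's envelope peak is at ``np.argmax(np.abs(waveform))``.  If
    the spec carries a double-click lag, an attenuated replica is
    appended at that lag.

    Raises
    ------
    ValueError
        If ``sample_rate`` is below twice the upper sweep frequency
        (Nyquist violation).
    """
    hi = spec.band_hz[1]
    if sample_rate < 2.0 * hi:
        raise ValueError(
            f"sample rate {sample_rate:g} Hz is below the Nyquist requirement "
            f"{2.0 * hi:g} Hz for a click sweeping to {hi:g} Hz"
        )
    T, peak_frac, roll = _calibrated_design(spec, sample_rate)
    if amplitude == 0.0:
        n = max(int(round(T * sample_rate)), 4) + 2 * int(round(0.0015 * sample_rate))
        return np.zeros(n)
    x = _synth_core(spec, sample_rate, T, peak_frac, roll)
    if spec.double_click_delay_us is not None:
        lag = int(round(spec.double_click_delay_us * 1e-6 * sample_rate))
        g = 10.0 ** (-spec.double_click_atten_db / 20.0)
        y = np.zeros(len(x) + lag)
        y[: len(x)] = x
        y[lag:] += g * x
        x = y / np.abs(y).max()
    return amplitude * x


# ---------------------------------------------------------------------------
# click trains

@dataclass
class TrainTruth:
    """Ground truth for one generated train: envelope-peak onset times (s),
    the generating spec, and the realised amplitude scale."""

    onsets_s: np.ndarray
    spec: ClickSpec
    snr_db: float
    amplitude: float

    @property
    def ici_s(self) -> np.ndarray:
        return np.diff(self.onsets_s)


def _draw_icis(spec: ClickSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    floor = max(2.0 * spec.duration_us * 1e-6, 1e-3)
    if spec.ici_lognormal:
        icis = rng.lognormal(math.log(spec.ici_s_mean), spec.ici_s_sd, size=n)
        return np.maximum(icis, floor)
    icis = rng.normal(spec.ici_s_mean, spec.ici_s_sd, size=n)
    for _ in range(100):
        bad = icis <= floor
        if not bad.any():
            break
        icis[bad] = rng.normal(spec.ici_s_mean, spec.ici_s_sd, size=int(bad.sum()))
    return np.maximum(icis, floor)


def _place_train(
    wave: np.ndarray,
    fs: float,
    spec: ClickSpec,
    n_clicks: int,
    rng: np.random.Generator,
    sigma_band: float,
    snr_db: float,
    t_start_s: Optional[float] = None,
) -> np.ndarray:
    """Add a calibrated click train to ``wave`` in place; return onset times."""
    click = make_click_waveform(spec, fs)
    band = snr_calibration_band(spec)
    p_band = float(np.abs(signal.sosfiltfilt(_bandpass_sos(band, fs), click)).max())
    amp = sigma_band * 10.0 ** (snr_db / 20.0) / p_band
    click = amp * click
    peak_idx = int(np.argmax(np.abs(click)))

    icis = _draw_icis(spec, n_clicks - 1, rng) if n_clicks > 1 else np.empty(0)
    span = float(icis.sum())
    duration_s = len(wave) / fs
    lead = peak_idx / fs + 0.002
    tail = (len(click) - peak_idx) / fs + 0.002
    slack = duration_s - lead - tail - span
    if slack <= 0:
        raise ValueError(
            f"train of {n_clicks} clicks (span {span:.2f} s) cannot fit in "
            f"{duration_s:.2f} s"
        )
    if t_start_s is None:
        t0 = lead + rng.random() * slack
    else:
        t0 = min(max(t_start_s, lead), lead + slack)
    onsets = t0 + np.concatenate([[0.0], np.cumsum(icis)])
    for t in onsets:
        i0 = int(round(t * fs)) - peak_idx
        wave[i0:i0 + len(click)] += click
    return onsets


def make_click_train(
    spec: ClickSpec,
    n_clicks: int,
    duration_s: float,
    sample_rate: float,
    noise: NoiseModel = NoiseModel(),
    seed: Optional[int] = None,
    snr_db: Optional[float] = None,
) -> tuple[np.ndarray, TrainTruth]:
    """Generate a noisy click train and its ground truth.

    Clicks are placed with ICIs drawn from the spec's interval model and
    scaled so the measured band-limited SNR_0-p of each click against the
    realised noise matches ``snr_db`` (default: the spec's target).

    Raises
    ------
    ValueError
        If the requested train cannot fit inside ``duration_s``.
    """
    if n_clicks < 1:
        raise ValueError("n_clicks must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    wave = make_noise(n, sample_rate, noise, rng)
    band = snr_calibration_band(spec)
    sigma = band_rms(wave, sample_rate, band) if noise.rms > 0 else 1.0
    target = spec.snr_db if snr_db is None else snr_db
    onsets = _place_train(wave, sample_rate, spec, n_clicks, rng, sigma, target)
    amp = sigma * 10.0 ** (target / 20.0)
    return wave, TrainTruth(onsets_s=onsets, spec=spec, snr_db=target, amplitude=amp)


# ---------------------------------------------------------------------------
# missions

@dataclass(frozen=True)
class MissionScenario:
    """Layout and statistical conditions of a simulated glider mission.

    ``prevalence`` maps preset names to the fraction of files containing
    that class; ``diel_profile`` optionally scales a class's prevalence
    by local hour (dict: class -> 24 multipliers, mean ~1).  Recording is
    structured as ``n_dives`` dives of ``files_per_dive`` consecutive
    files with a surface gap between dives, emulating a glider that
    records only on the deep part of each dive.
    """

    n_dives: int
    files_per_dive: int
    prevalence: dict[str, float]
    diel_profile: Optional[dict[str, Sequence[float]]] = None
    sample_rate_hz: float = 194_000.0
    file_duration_s: float = 60.0
    # timestamp spacing between files; defaults to file_duration_s.  A
    # scaled-down mission can keep real minute-file timestamps (60 s
    # stride) while generating shorter audio per file.
    file_stride_s: Optional[float] = None
    start_utc: str = "2009-10-27T06:00:00+00:00"
    utc_offset_h: float = -10.0
    surface_gap_min: float = 16.2
    noise: NoiseModel = field(default_factory=NoiseModel)
    snr_db: Optional[dict[str, float]] = None
    clicks_range: tuple[int, int] = (8, 18)

    def __post_init__(self) -> None:
        for cls, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {cls!r} must be in [0, 1]")
            hi = get_preset(cls).band_hz[1]
            if self.sample_rate_hz < 2.0 * hi:
                raise ValueError(
                    f"sample rate {self.sample_rate_hz:g} Hz below Nyquist for {cls!r}"
                )
        if self.diel_profile is not None:
            for cls, mult in self.diel_profile.items():
                if len(mult) != 24:
                    raise ValueError("diel_profile entries need 24 hourly multipliers")

    @property
    def n_files(self) -> int:
        return self.n_dives * self.files_per_dive

    @property
    def start_dt(self) -> datetime:
        return datetime.fromisoformat(self.start_utc)


@dataclass
class FileMeta:
    file_id: str
    dive_id: int
    start_utc: datetime
    duration_s: float
    sample_rate_hz: float


def _file_schedule(scenario: MissionScenario) -> list[FileMeta]:
    metas = []
    t = scenario.start_dt
    idx = 0
    stride = scenario.file_stride_s or scenario.file_duration_s
    dive_span = scenario.files_per_dive * stride
    for d in range(scenario.n_dives):
        for f in range(scenario.files_per_dive):
            start = t + timedelta(seconds=f * stride)
            name = f"pam{idx:04d}_DIVE{d:02d}_{start:%Y%m%d-%H%M%S}"
            metas.append(
                FileMeta(name, d, start, scenario.file_duration_s, scenario.sample_rate_hz)
            )
            idx += 1
        t = t + timedelta(seconds=dive_span + scenario.surface_gap_min * 60.0)
    return metas


def iter_mission(
    scenario: MissionScenario,
    seed: Optional[int] = None,
    specs: Optional[dict[str, ClickSpec]] = None,
) -> Iterator[tuple[FileMeta, np.ndarray, pd.DataFrame]]:
    """Yield ``(meta, samples, truth)`` per simulated minute file.

    ``truth`` has one row per placed click: file_id, species, onset_s.
    Streaming generation keeps a full mission's audio out of memory.
    """
    specs = dict(PRESETS if specs is None else specs)
    rng = np.random.default_rng(seed)
    fs = scenario.sample_rate_hz
    n = int(round(scenario.file_duration_s * fs))
    for meta in _file_schedule(scenario):
        wave = make_noise(n, fs, scenario.noise, rng)
        sigma_cache: dict[tuple[float, float], float] = {}
        local_hour = int((meta.start_utc + timedelta(hours=scenario.utc_offset_h)).hour)
        rows = []
        for cls, p in scenario.prevalence.items():
            mult = 1.0
            if scenario.diel_profile is not None and cls in scenario.diel_profile:
                mult = float(scenario.diel_profile[cls][local_hour])
            if rng.random() >= min(1.0, p * mult):
                continue
            spec = specs[cls]
            band = snr_calibration_band(spec)
            if band not in sigma_cache:
                sigma_cache[band] = (
                    band_rms(wave, fs, band) if scenario.noise.rms > 0 else 1.0
                )
            snr = spec.snr_db
            if scenario.snr_db and cls in scenario.snr_db:
                snr = scenario.snr_db[cls]
            lo_n, hi_n = scenario.clicks_range
            n_clicks = int(rng.integers(lo_n, hi_n + 1))
            # shrink to fit short files
            max_fit = int((scenario.file_duration_s - 0.5) / max(spec.ici_s_mean, 1e-3))
            n_clicks = max(3, min(n_clicks, max_fit))
            try:
                onsets = _place_train(
                    wave, fs, spec, n_clicks, rng, sigma_cache[band], snr
                )
            except ValueError:
                continue  # pathological short file; leave class absent
            rows.extend(
                {"file_id": meta.file_id, "species": cls, "onset_s": float(t)}
                for t in onsets
            )
        truth = pd.DataFrame(rows, columns=["file_id", "species", "onset_s"])
        yield meta, wave, truth


def truth_flags(truth: pd.DataFrame, file_ids: Sequence[str]) -> pd.DataFrame:
    """Per-file boolean presence table from a truth click table."""
    classes = sorted(truth["species"].unique()) if len(truth) else []
    flags = pd.DataFrame(False, index=pd.Index(file_ids, name="file_id"), columns=classes)
    for (fid, cls), _ in truth.groupby(["file_id", "species"]):
        flags.loc[fid, cls] = True
    return flags


def make_mission(
    scenario: MissionScenario,
    out_dir: str | Path,
    seed: Optional[int] = None,
    specs: Optional[dict[str, ClickSpec]] = None,
) -> pd.DataFrame:
    """Write a simulated mission (PCM-16 WAV minute files + truth CSV).

    Returns the truth table; files land in ``out_dir``.
    """
    from .audio import write_wav

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_truth = []
    for meta, wave, truth in iter_mission(scenario, seed=seed, specs=specs):
        write_wav(out / f"{meta.file_id}.wav", wave, scenario.sample_rate_hz)
        all_truth.append(truth)
    df = (
        pd.concat(all_truth, ignore_index=True)
        if all_truth
        else pd.DataFrame(columns=["file_id", "species", "onset_s"])
    )
    df.to_csv(out / "truth.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# simulated whale tag tracks and glider tracks

_KM_PER_DEG_LAT = 111.19


def make_tag_track(
    n_deep_dives: int,
    dive_params: Optional[dict] = None,
    start_pos: tuple[float, float] = (19.7, -156.2),
    drift: tuple[float, float] = (330.0, 0.5),
    seed: Optional[int] = None,
    start_utc: str = "2009-11-03T12:00:00+00:00",
    argos_error_km: float = 0.0,
    accuracy_radius_km: float = 1.5,
    track_dt_s: float = 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a satellite-tagged whale performing deep dives only.

    One ARGOS fix is produced per surfacing, timed at the centre of the
    surface interval; fix positions are the true position plus isotropic
    Gaussian error of scale ``argos_error_km``.  ``drift`` is (course
    degrees true, speed m/s).  Returns ``(fixes, track)`` where ``track``
    is the true continuous position/depth series.
    """
    p = {
        "deep_dive_duration_s": 3480.0,  # ~58 min foraging dives
        "surface_duration_s": 120.0,
        "vocal_depth_floor_m": 400.0,
        "descent_rate_mps": 1.1,
        "ascent_rate_mps": 0.8,
    }
    if dive_params:
        p.update(dive_params)
    rng = np.random.default_rng(seed)
    t0 = datetime.fromisoformat(start_utc)
    cycle = p["deep_dive_duration_s"] + p["surface_duration_s"]
    total_s = n_deep_dives * cycle + p["surface_duration_s"]
    tt = np.arange(0.0, total_s + track_dt_s, track_dt_s)

    course = math.radians(drift[0])
    v_north_kms = drift[1] * math.cos(course) / 1000.0
    v_east_kms = drift[1] * math.sin(course) / 1000.0
    lat0, lon0 = start_pos
    lat = lat0 + v_north_kms * tt / _KM_PER_DEG_LAT
    lon = lon0 + v_east_kms * tt / (_KM_PER_DEG_LAT * np.cos(math.radians(lat0)))

    depth = np.zeros_like(tt)
    surf = p["surface_duration_s"]
    for i, t in enumerate(tt):
        tc = (t - surf) % cycle if t >= surf else -1.0
        if tc < 0:
            depth[i] = 0.0
            continue
        if tc >= p["deep_dive_duration_s"]:
            depth[i] = 0.0
            continue
        rd, ra = p["descent_rate_mps"], p["ascent_rate_mps"]
        L = p["deep_dive_duration_s"]
        t_turn = L * ra / (rd + ra)
        depth[i] = rd * tc if tc <= t_turn else ra * (L - tc)
    track = pd.DataFrame(
        {
            "time": [t0 + timedelta(seconds=float(s)) for s in tt],
            "lat": lat,
            "lon": lon,
            "depth_m": depth,
        }
    )

    fix_rows = []
    # surface intervals: [0, surf], then after each dive
    centers = [surf / 2.0 + k * cycle for k in range(n_deep_dives + 1)]
    for c in centers:
        if c > total_s:
            break
        la = lat0 + v_north_kms * c / _KM_PER_DEG_LAT
        lo = lon0 + v_east_kms * c / (_KM_PER_DEG_LAT * math.cos(math.radians(lat0)))
        if argos_error_km > 0:
            la += rng.normal(0.0, argos_error_km / math.sqrt(2)) / _KM_PER_DEG_LAT
            lo += rng.normal(0.0, argos_error_km / math.sqrt(2)) / (
                _KM_PER_DEG_LAT * math.cos(math.radians(lat0))
            )
        fix_rows.append(
            {
                "time": t0 + timedelta(seconds=float(c)),
                "lat": la,
                "lon": lo,
                "accuracy_radius_km": accuracy_radius_km,
            }
        )
    return pd.DataFrame(fix_rows), track


def make_glider_track(
    n_dives: int,
    dive_duration_s: float = 4.3 * 3600.0,
    surface_duration_s: float = 16.2 * 60.0,
    max_depth_m: float = 1000.0,
    record_below_m: float = 500.0,
    start_pos: tuple[float, float] = (19.7, -156.3),
    course_deg: float = 330.0,
    speed_mps: float = 0.25,
    dt_s: float = 60.0,
    start_utc: str = "2009-11-03T00:00:00+00:00",
) -> pd.DataFrame:
    """Simulate a glider survey track with v-shaped dives.

    ``recording`` is True where depth exceeds ``record_below_m``,
    emulating an acoustic system operated only on the deep segment of
    each dive.
    """
    t0 = datetime.fromisoformat(start_utc)
    cycle = dive_duration_s + surface_duration_s
    total = n_dives * cycle
    tt = np.arange(0.0, total, dt_s)
    course = math.radians(course_deg)
    lat0, lon0 = start_pos
    lat = lat0 + speed_mps * np.cos(course) * tt / 1000.0 / _KM_PER_DEG_LAT
    lon = lon0 + speed_mps * np.sin(course) * tt / 1000.0 / (
        _KM_PER_DEG_LAT * math.cos(math.radians(lat0))
    )
    tc = tt % cycle
    half = dive_duration_s / 2.0
    depth = np.where(
        tc < dive_duration_s,
        np.where(tc <= half, max_depth_m * tc / half, max_depth_m * (dive_duration_s - tc) / half),
        0.0,
    )
    return pd.DataFrame(
        {
            "time": [t0 + timedelta(seconds=float(s)) for s in tt],
            "lat": lat,
            "lon": lon,
            "depth_m": depth,
            "recording": depth >= record_below_m,
        }
    )
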