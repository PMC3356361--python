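"""Per-click and per-train feature measurement.

The discriminating features are the ones an analyst uses to separate
beaked-whale clicks from other odontocete transients: click duration,
the -20 dB low-frequency roll-off of the spectrum, spectral peak
frequency, presence and slope of the FM upsweep, the band-limited
zero-to-peak signal-to-noise ratio (SNR_0-p), and the inter-click
interval (ICI) series of the train.

Conventions
-----------
duration
    Length of the interval containing the central 95 % of the energy of
    the 10 kHz-high-pass-filtered click, measured inside an
    envelope-gated region around the click (the contiguous span where
    the smoothed Hilbert envelope stays above a floor tied to the local
    noise level, padded).  The expected noise-energy ramp is subtracted
    from the cumulative energy, so additive in-band noise neither
    widens nor shifts the interval systematically.
low-frequency roll-off
    Scanning the noise-corrected magnitude spectrum upward from
    ``fmin``, the lowest frequency at which the level first comes
    within 20 dB of the peak.  A -20 dB point sits well below the
    in-band noise floor of a single noisy click, so the spectrum used
    is the click power spectrum minus a noise power spectrum estimated
    from adjacent click-free samples with the identical window length;
    train-level values average the spectra of all clicks first.
upsweep
    Least-squares slope of the spectrogram ridge (per-frame argmax
    frequency) across the click, using the fine 32/128-sample framing;
    positive slope over at least 3 frames counts as an upsweep.
SNR_0-p
    20 log10 of the band-limited (15-90 kHz) peak amplitude of the
    click over the RMS of an adjacent click-free noise window, the peak
    taken inside the envelope-gated click region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .detect import ClickEvent, SpectrogramConfig, spectrogram

log = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "ClickFeatures",
    "ClickTrain",
    "energy_duration_s",
    "measure_duration",
    "click_spectrum",
    "lf_rolloff",
    "peak_frequency",
    "upsweep_test",
    "snr0p",
    "ici_series",
    "measure_click",
    "measure_train",
]

SNR_BAND_HZ = (15_000.0, 90_000.0)


@dataclass(frozen=True)
class FeatureConfig:
    """Measurement conventions (see module docstring for definitions)."""

    highpass_hz: float = 10_000.0
    duration_fraction: float = 0.95
    envelope_smooth_s: float = 5e-5
    gate_rel_floor: float = 0.1       # envelope gate: fraction of envelope peak
    gate_noise_mult: float = 1.8      # ... or this multiple of the noise envelope
    gate_pad_s: float = 2.5e-4
    analysis_halfwin_s: float = 0.0015
    noise_gap_s: float = 0.001
    noise_window_s: float = 0.005
    nfft: int = 4096
    smooth_bins: int = 5
    rolloff_drop_db: float = 20.0
    rolloff_fmin_hz: float = 10_000.0
    peak_fmin_hz: float = 3_000.0
    snr_band_hz: tuple[float, float] = SNR_BAND_HZ
    upsweep_fmin_hz: float = 10_000.0
    upsweep_energy_floor: float = 0.15


@dataclass
class ClickFeatures:
    """Measured features of one click."""

    duration_us: float
    peak_freq_hz: float
    lf_rolloff_hz: float  # nan when the spectrum never reaches -20 dB
    upsweep: Optional[bool]  # None when the contour is indeterminate
    upsweep_slope_khz_per_ms: float
    snr0p_db: float


@dataclass
class ClickTrain:
    """An ordered click train: ICI series, per-click features, and
    train-level estimates from the coherently stacked click (clicks of
    one train aligned by cross-correlation and averaged, which lowers
    the noise power by 1/n)."""

    events: list[ClickEvent]
    features: list[ClickFeatures]
    ici_s: np.ndarray
    ici_mean_s: float
    ici_sd_s: float
    peak_freq_hz: float = math.nan
    lf_rolloff_hz: float = math.nan
    duration_us: float = math.nan  # stacked-click duration

    @property
    def n_clicks(self) -> int:
        return len(self.events)

    @property
    def file_ids(self) -> list[str]:
        return sorted({ev.file_id for ev in self.events})

    def _med(self, attr: str) -> float:
        vals = [getattr(f, attr) for f in self.features]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        return float(np.median(vals)) if vals else math.nan

    @property
    def duration_us_med(self) -> float:
        return self._med("duration_us")

    @property
    def snr_db_med(self) -> float:
        return self._med("snr0p_db")

    @property
    def upsweep_slope_med(self) -> float:
        return self._med("upsweep_slope_khz_per_ms")

    @property
    def upsweep_frac(self) -> float:
        votes = [f.upsweep for f in self.features if f.upsweep is not None]
        return float(np.mean(votes)) if votes else math.nan

    @property
    def upsweep(self) -> Optional[bool]:
        frac = self.upsweep_frac
        return None if math.isnan(frac) else frac >= 0.5

    def summary(self) -> dict:
        return {
            "n_clicks": self.n_clicks,
            "ici_mean_s": self.ici_mean_s,
            "ici_sd_s": self.ici_sd_s,
            "duration_us_med": self.duration_us_med,
            "duration_us_stack": self.duration_us,
            "peak_freq_hz_med": self.peak_freq_hz,
            "lf_rolloff_hz_med": self.lf_rolloff_hz,
            "upsweep_frac": self.upsweep_frac,
            "upsweep_slope_khz_per_ms_med": self.upsweep_slope_med,
            "snr_db_med": self.snr_db_med,
        }


# ---------------------------------------------------------------------------
# primitives

def _highpass(x: np.ndarray, fs: float, cutoff: Optional[float]) -> np.ndarray:
    if not cutoff:
        return np.asarray(x, dtype=float)
    sos = signal.butter(4, cutoff, "highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _envelope(x: np.ndarray, fs: float, smooth_s: float) -> np.ndarray:
    env = np.abs(signal.hilbert(x))
    return _smooth(env, max(1, int(round(smooth_s * fs))))


def _gate_region(
    env: np.ndarray, fs: float, cfg: FeatureConfig, noise_env: float
) -> tuple[int, int]:
    """Contiguous region around the envelope peak where the click lives."""
    k = int(np.argmax(env))
    thr = max(cfg.gate_rel_floor * env[k], cfg.gate_noise_mult * noise_env)
    i0 = k
    while i0 > 0 and env[i0 - 1] > thr:
        i0 -= 1
    i1 = k
    while i1 + 1 < len(env) and env[i1 + 1] > thr:
        i1 += 1
    pad = int(round(cfg.gate_pad_s * fs))
    return max(0, i0 - pad), min(len(env), i1 + 1 + pad)


def energy_duration_s(
    x: np.ndarray,
    sample_rate: float,
    fraction: float = 0.95,
    noise_power: float = 0.0,
) -> float:
    """Duration of the interval holding the central ``fraction`` of energy.

    ``noise_power`` (mean squared noise per sample, same filtering as
    ``x``) subtracts the expected noise-energy ramp before the quantile
    scan, which keeps additive noise from widening the interval.
    """
    x = np.asarray(x, dtype=float)
    e = np.cumsum(x * x)
    if noise_power > 0.0:
        e = e - noise_power * np.arange(1, len(x) + 1)
        e = np.maximum.accumulate(np.maximum(e, 0.0))
    tot = e[-1]
    if tot <= 0:
        return 0.0
    q = (1.0 - fraction) / 2.0
    i_lo = int(np.searchsorted(e, q * tot))
    i_hi = int(np.searchsorted(e, (1.0 - q) * tot))
    return (i_hi - i_lo) / sample_rate


def measure_duration(
    click_window: np.ndarray,
    sample_rate: float,
    highpass_hz: Optional[float] = 10_000.0,
    noise_window: Optional[np.ndarray] = None,
    fraction: float = 0.95,
    cfg: FeatureConfig = FeatureConfig(),
) -> float:
    """Click duration in microseconds (95 %-energy convention).

    On a clean window this is the plain central-energy interval; when a
    noise window is supplied, the measurement is restricted to the
    envelope-gated click region and noise-ramp corrected.

    Raises
    ------
    ValueError
        For an all-zero window.
    """
    x = np.asarray(click_window, dtype=float)
    if not np.any(x):
        raise ValueError("cannot measure duration of an all-zero window")
    xf = _highpass(x, sample_rate, highpass_hz)
    npow = 0.0
    noise_env = 0.0
    if noise_window is not None and len(noise_window):
        nf = _highpass(np.asarray(noise_window, dtype=float), sample_rate, highpass_hz)
        npow = float(np.mean(nf * nf))
        noise_env = 1.25 * math.sqrt(npow)  # mean Rayleigh envelope of Gaussian noise
    env = _envelope(xf, sample_rate, cfg.envelope_smooth_s)
    i0, i1 = _gate_region(env, sample_rate, cfg, noise_env)
    return energy_duration_s(xf[i0:i1], sample_rate, fraction, npow) * 1e6


def click_spectrum(
    click_window: np.ndarray,
    sample_rate: float,
    nfft: int = 4096,
    smooth_bins: int = 5,
    noise_window: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrum of an isolated click window, optionally
    noise-corrected.

    A direct (zero-padded) FFT is used rather than spectrogram columns:
    the coarse display bandwidth of the fine click framing cannot
    resolve a 20 vs 25 kHz roll-off.  When ``noise_window`` is given,
    its average power spectrum — estimated from sub-windows of the same
    length as the click window — is subtracted in the power domain
    before taking the magnitude.
    """
    x = np.asarray(click_window, dtype=float)
    nfft = max(nfft, len(x))
    power = np.abs(np.fft.rfft(x, nfft)) ** 2
    if noise_window is not None and len(noise_window) >= len(x):
        npsd = _noise_power_spectrum(np.asarray(noise_window, float), len(x), nfft)
        power = np.maximum(power - npsd, 1e-8 * power.max())
        # smooth over ~2 independent spectral widths (fs/len(x)) so noise
        # residuals average out rather than tripping level scans
        smooth_bins = max(smooth_bins, int(round(2 * nfft / max(len(x), 1))) | 1)
    power = _smooth(power, smooth_bins)
    freqs = np.fft.rfftfreq(nfft, 1.0 / sample_rate)
    return freqs, np.sqrt(power)


def _noise_power_spectrum(noise: np.ndarray, wlen: int, nfft: int) -> np.ndarray:
    """Average power spectrum of ``wlen``-sample noise windows (same
    windowing convention as the click FFT, so it subtracts directly)."""
    hops = max(1, wlen // 2)
    segs = [
        noise[i : i + wlen]
        for i in range(0, max(1, len(noise) - wlen + 1), hops)
    ]
    acc = np.zeros(nfft // 2 + 1)
    for s in segs:
        acc += np.abs(np.fft.rfft(s, nfft)) ** 2
    return acc / len(segs)


def lf_rolloff(
    freqs_hz: np.ndarray,
    mags: np.ndarray,
    drop_db: float = 20.0,
    fmin_hz: float = 10_000.0,
    fmax_hz: Optional[float] = None,
    noise_floor_mags: Optional[np.ndarray] = None,
    floor_mult: float = 2.0,
) -> float:
    """Low-frequency roll-off: scanning upward from ``fmin_hz``, the
    lowest frequency whose level first rises to within ``drop_db`` of the
    spectral peak.

    When ``noise_floor_mags`` (same grid as ``mags``) is given, the scan
    level is floor-limited: the spectrum must also rise ``floor_mult``
    above the local noise floor, since a -20 dB point lying below the
    measurable floor cannot be observed — the scan then reports where
    the spectrum first emerges from the noise.  Returns NaN (logged) if
    no level qualifies.
    """
    f = np.asarray(freqs_hz, dtype=float)
    m = np.asarray(mags, dtype=float)
    hi = fmax_hz if fmax_hz is not None else f[-1] * 0.97
    mask = (f >= fmin_hz) & (f <= hi)
    if not mask.any() or not np.any(m[mask] > 0):
        log.warning("roll-off undefined: empty or silent spectrum")
        return math.nan
    sub_f, sub_m = f[mask], m[mask]
    peak = sub_m.max()
    thresh = np.full_like(sub_m, peak * 10.0 ** (-drop_db / 20.0))
    if noise_floor_mags is not None:
        floor = np.asarray(noise_floor_mags, dtype=float)[mask]
        thresh = np.maximum(thresh, floor_mult * floor)
    idx = np.nonzero(sub_m >= thresh)[0]
    if idx.size == 0:
        log.warning("roll-off undefined: spectrum never within %g dB of peak", drop_db)
        return math.nan
    return float(sub_f[idx[0]])


def peak_frequency(
    freqs_hz: np.ndarray,
    mags: np.ndarray,
    fmin_hz: float = 3_000.0,
    fmax_hz: Optional[float] = None,
) -> float:
    """Frequency of the spectral maximum within the scan range."""
    f = np.asarray(freqs_hz, dtype=float)
    m = np.asarray(mags, dtype=float)
    hi = fmax_hz if fmax_hz is not None else f[-1] * 0.97
    mask = (f >= fmin_hz) & (f <= hi)
    return float(f[mask][np.argmax(m[mask])])


def upsweep_test(
    click_window: np.ndarray,
    sample_rate: float,
    fine_cfg: Optional[SpectrogramConfig] = None,
    fmin_hz: float = 10_000.0,
    energy_floor: float = 0.1,
    slope_eps_khz_per_ms: float = 1.0,
) -> tuple[Optional[bool], float]:
    """FM-contour test on the fine spectrogram ridge.

    Returns ``(upsweep, slope_khz_per_ms)``: the least-squares slope of
    the per-frame argmax frequency across the frames covering the click
    (contiguous run, frame energy within ``energy_floor`` of the peak
    frame, containing the peak frame).  ``upsweep`` is True for positive
    slope (beyond a small deadband ``slope_eps_khz_per_ms`` absorbing
    ridge-quantisation jitter) over >= 3 frames, False otherwise, and
    None (indeterminate) when fewer than 3 frames cover the click.
    """
    cfg = fine_cfg or SpectrogramConfig.click_fine(sample_rate)
    x = np.asarray(click_window, dtype=float)
    if len(x) < cfg.frame_size:
        return None, math.nan
    freqs, times, mag = spectrogram(x, cfg)
    rows = freqs >= fmin_hz
    power = mag[rows] ** 2
    col_e = power.sum(axis=0)
    if col_e.max() <= 0:
        return None, math.nan
    kmax = int(np.argmax(col_e))
    keep = col_e >= energy_floor * col_e[kmax]
    i0 = kmax
    while i0 > 0 and keep[i0 - 1]:
        i0 -= 1
    i1 = kmax
    while i1 + 1 < len(keep) and keep[i1 + 1]:
        i1 += 1
    cols = np.arange(i0, i1 + 1)
    if cols.size < 3:
        return None, math.nan
    ridge_khz = freqs[rows][np.argmax(power[:, cols], axis=0)] / 1e3
    t_ms = times[cols] * 1e3
    # energy-weighted fit: frames dominated by noise contribute little
    w = np.sqrt(col_e[cols] / col_e[kmax])
    slope = float(np.polyfit(t_ms, ridge_khz, 1, w=w)[0])
    return slope > slope_eps_khz_per_ms, slope


def snr0p(
    click_window: np.ndarray,
    noise_window: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = SNR_BAND_HZ,
) -> float:
    """Band-limited zero-to-peak SNR in dB.

    20 log10 of the band-passed click window's peak absolute amplitude
    over the band-passed noise window's RMS.  Pass a window tight
    around the click: noise maxima in a long window otherwise masquerade
    as the click peak at low SNR.

    Raises
    ------
    ValueError
        For a silent noise window.
    """
    lo = max(band[0], 10.0)
    hi = min(band[1], 0.985 * sample_rate / 2.0)
    sos = signal.butter(4, [lo, hi], "bandpass", fs=sample_rate, output="sos")
    nz = np.asarray(noise_window, dtype=float)
    if nz.size == 0 or not np.any(nz):
        raise ValueError("silent noise window: SNR_0-p undefined")
    c = signal.sosfiltfilt(sos, np.asarray(click_window, dtype=float))
    n = signal.sosfiltfilt(sos, nz)
    rms = float(np.sqrt(np.mean(n * n)))
    if rms == 0.0:
        raise ValueError("silent noise window: SNR_0-p undefined")
    return 20.0 * math.log10(float(np.abs(c).max()) / rms)


def ici_series(onsets_s: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """ICI list, mean and sample SD from click onset times.

    Onsets are sorted first (order invariance); fewer than 2 clicks give
    an empty series with NaN mean/SD.
    """
    t = np.sort(np.asarray(list(onsets_s), dtype=float))
    if t.size < 2:
        return np.empty(0), math.nan, math.nan
    ici = np.diff(t)
    sd = float(np.std(ici, ddof=1)) if ici.size > 1 else 0.0
    return ici, float(np.mean(ici)), sd


# ---------------------------------------------------------------------------
# per-event / per-train drivers

def _event_windows(ev: ClickEvent, cfg: FeatureConfig):
    """(analysis window, noise window, offsets) for one event."""
    fs = ev.sample_rate_hz
    onset_idx = int(round((ev.onset_s - ev.window_start_s) * fs))
    w = ev.window

    def clamp(i):
        return max(0, min(len(w), i))

    d = int(round(cfg.analysis_halfwin_s * fs))
    a0, a1 = clamp(onset_idx - d), clamp(onset_idx + d)
    gap = int(round(cfg.noise_gap_s * fs))
    nlen = int(round(cfg.noise_window_s * fs))
    n1 = clamp(a0 - gap)
    noise = w[clamp(n1 - nlen) : n1]
    return w[a0:a1], noise


def _click_region(
    awin: np.ndarray, noise: Optional[np.ndarray], fs: float, cfg: FeatureConfig
) -> tuple[int, int, float]:
    """Envelope-gated click region within the analysis window and the
    noise power (per sample, high-passed domain)."""
    xf = _highpass(awin, fs, cfg.highpass_hz)
    npow = 0.0
    if noise is not None and len(noise) > 8:
        nf = _highpass(noise, fs, cfg.highpass_hz)
        npow = float(np.mean(nf * nf))
    env = _envelope(xf, fs, cfg.envelope_smooth_s)
    i0, i1 = _gate_region(env, fs, cfg, 1.25 * math.sqrt(npow))
    return i0, i1, npow


def measure_click(ev: ClickEvent, cfg: FeatureConfig = FeatureConfig()) -> ClickFeatures:
    """Measure all per-click features from a detected event's window."""
    fs = ev.sample_rate_hz
    awin, noise = _event_windows(ev, cfg)
    have_noise = noise is not None and len(noise) > 8
    duration = measure_duration(
        awin, fs, cfg.highpass_hz, noise if have_noise else None,
        cfg.duration_fraction, cfg,
    )
    i0, i1, _ = _click_region(awin, noise if have_noise else None, fs, cfg)
    region = awin[i0:i1]
    freqs, mags = click_spectrum(
        region, fs, cfg.nfft, cfg.smooth_bins, noise if have_noise else None
    )
    roll = lf_rolloff(freqs, mags, cfg.rolloff_drop_db, cfg.rolloff_fmin_hz)
    peak = peak_frequency(freqs, mags, cfg.peak_fmin_hz)
    up, slope = upsweep_test(
        awin, fs, fmin_hz=cfg.upsweep_fmin_hz, energy_floor=cfg.upsweep_energy_floor
    )
    snr = snr0p(region, noise, fs, cfg.snr_band_hz) if have_noise else math.nan
    return ClickFeatures(
        duration_us=duration,
        peak_freq_hz=peak,
        lf_rolloff_hz=roll,
        upsweep=up,
        upsweep_slope_khz_per_ms=slope,
        snr0p_db=snr,
    )


def _stack_clicks(
    segs: list[np.ndarray], max_shift: int = 64
) -> tuple[np.ndarray, int]:
    """Coherently average click segments after cross-correlation alignment."""
    ref = max(segs, key=lambda s: float(np.abs(s).max()))
    acc = np.zeros(len(ref))
    n = 0
    for seg in segs:
        if len(seg) != len(ref):
            continue
        corr = signal.correlate(ref, seg, mode="full")
        mid = len(seg) - 1
        lo, hi = mid - max_shift, mid + max_shift + 1
        shift = int(np.argmax(corr[lo:hi])) - max_shift
        acc += np.roll(seg, shift)
        n += 1
    return (acc / n if n else acc), n


def measure_train(
    events: Sequence[ClickEvent], cfg: FeatureConfig = FeatureConfig()
) -> ClickTrain:
    """Measure a grouped click train.

    Per-click features are measured individually.  Train-level duration,
    peak frequency and low-frequency roll-off come from the coherently
    stacked click: segments of a common length centred on each click's
    envelope peak are aligned by cross-correlation and averaged, which
    reduces the noise power by the number of clicks, and the stacked
    spectrum is noise-corrected with a floor-aware roll-off scan.
    """
    evs = sorted(events, key=lambda e: e.onset_s)
    feats = [measure_click(ev, cfg) for ev in evs]
    ici, mean, sd = ici_series([e.onset_s for e in evs])

    regions, noises = [], []
    for ev in evs:
        awin, noise = _event_windows(ev, cfg)
        have_noise = noise is not None and len(noise) > 8
        i0, i1, _ = _click_region(awin, noise if have_noise else None, ev.sample_rate_hz, cfg)
        regions.append((awin, i0, i1))
        noises.append(noise if have_noise else np.empty(0))
    fs = evs[0].sample_rate_hz if evs else 0.0
    lengths = [i1 - i0 for _, i0, i1 in regions]
    wlen = int(np.clip(np.median(lengths), 48, 1024)) if lengths else 0
    peak_hz = roll_hz = dur_us = math.nan
    if wlen >= 48:
        segs = []
        for awin, i0, i1 in regions:
            mid = (i0 + i1) // 2
            j0 = max(0, min(mid - wlen // 2, len(awin) - wlen))
            seg = awin[j0 : j0 + wlen]
            if len(seg) == wlen:
                segs.append(seg)
        nacc = np.zeros(cfg.nfft // 2 + 1)
        npows = []
        n_noise = 0
        for noise in noises:
            if len(noise) >= wlen:
                nacc += _noise_power_spectrum(noise, wlen, cfg.nfft)
                nf = _highpass(noise, fs, cfg.highpass_hz)
                npows.append(float(np.mean(nf * nf)))
                n_noise += 1
        if segs:
            stacked, n_stk = _stack_clicks(segs)
            # duration of the stacked click (noise power reduced by 1/n)
            xf = _highpass(stacked, fs, cfg.highpass_hz)
            npow_stk = (float(np.mean(npows)) / n_stk) if npows else 0.0
            env = _envelope(xf, fs, cfg.envelope_smooth_s)
            g0, g1 = _gate_region(env, fs, cfg, 1.25 * math.sqrt(npow_stk))
            dur_us = energy_duration_s(
                xf[g0:g1], fs, cfg.duration_fraction, npow_stk
            ) * 1e6

            power = np.abs(np.fft.rfft(stacked, cfg.nfft)) ** 2
            width = cfg.smooth_bins
            floor_mags = None
            if n_noise:
                npsd_stk = nacc / n_noise / n_stk
                power = np.maximum(power - npsd_stk, 1e-8 * power.max())
                width = max(width, int(round(2 * cfg.nfft / wlen)) | 1)
                floor_mags = np.sqrt(_smooth(npsd_stk, width))
            power = _smooth(power, width)
            freqs = np.fft.rfftfreq(cfg.nfft, 1.0 / fs)
            mags = np.sqrt(power)
            peak_hz = peak_frequency(freqs, mags, cfg.peak_fmin_hz)
            roll_hz = lf_rolloff(
                freqs, mags, cfg.rolloff_drop_db, cfg.rolloff_fmin_hz,
                noise_floor_mags=floor_mags,
            )

    return ClickTrain(
        events=list(evs),
        features=feats,
        ici_s=ici,
        ici_mean_s=mean,
        ici_sd_s=sd,
        peak_freq_hz=peak_hz,
        lf_rolloff_hz=roll_hz,
        duration_us=dur_us,
    )
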