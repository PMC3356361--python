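"""PCM-16 WAV I/O and minute-file naming.

Files follow the glider convention ``pamNNNN_DIVEdd_YYYYMMDD-HHMMSS.wav``
(recording index, dive number, UTC start time).  Samples are stored as
16-bit PCM with full scale at 1.0.
"""

from __future__ import annotations

import re
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["write_wav", "read_wav", "parse_filename", "FILENAME_RE"]

FILENAME_RE = re.compile(
    r"pam(?P<index>\d{4})_DIVE(?P<dive>\d{2})_(?P<stamp>\d{8}-\d{6})\.wav$"
)


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: float) -> None:
    """Write float samples (full scale 1.0) as PCM-16 WAV."""
    clipped = np.clip(samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(round(sample_rate)), pcm)


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file to float64 samples in [-1, 1] and its sample rate.

    Raises
    ------
    OSError
        Naming the file, if it cannot be read.
    """
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise OSError(f"unreadable audio file: {path}") from exc
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483648.0
    else:
        x = data.astype(np.float64)
    if x.ndim > 1:
        x = x[:, 0]
    return x, float(rate)


def parse_filename(name: str) -> dict:
    """Parse ``pamNNNN_DIVEdd_YYYYMMDD-HHMMSS.wav`` into its fields."""
    m = FILENAME_RE.search(str(name))
    if not m:
        raise ValueError(f"filename does not match minute-file convention: {name}")
    stamp = datetime.strptime(m.group("stamp"), "%Y%m%d-%H%M%S").replace(
        tzinfo=timezone.utc
    )
    return {
        "index": int(m.group("index")),
        "dive_id": int(m.group("dive")),
        "start_utc": stamp,
    }
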