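"""Audio containers and WAV I/O.

Recordings are mono, 16-bit PCM at 250 kHz by default — the sampling setup
used for mouse-pup ultrasonic vocalizations, whose fundamentals sit between
~30 kHz and the 125 kHz Nyquist limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 250_000


@dataclass
class AudioSegment:
    """One call (or recording slice) as a float waveform.

    Parameters
    ----------
    samples : ndarray of float
        Mono waveform, full-scale in [-1, 1].
    sample_rate : int
        Sampling rate in Hz.
    label : str or None
        Call-class label, when known.
    strain : str or None
        Genotype of the emitting animal ("WT" or "KO"), when known.
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    label: str | None = None
    strain: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D mono waveform")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


def write_wav(path: str | Path, segment: AudioSegment) -> None:
    """Write a segment as 16-bit PCM WAV, clipping to full scale."""
    x = np.clip(segment.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(segment.sample_rate), pcm)


def read_wav(path: str | Path) -> AudioSegment:
    """Read a WAV file into an :class:`AudioSegment` (scaled to [-1, 1])."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioSegment(samples=samples, sample_rate=int(rate))
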