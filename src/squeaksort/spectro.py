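"""STFT spectrograms, threshold/hold-time call detection, image rendering.

Analysis defaults mirror a standard Avisoft-style setup for 250 kHz USV
recordings: 512-point FFT, Hamming window, 75% overlap (hop 128 samples),
giving 488.28 Hz frequency resolution and 0.512 ms time resolution, with a
30 kHz high-pass to suppress background noise.  Magnitudes are expressed in
dB relative to the recording maximum, so 0 dB is the loudest point of the
recording and everything else is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from skimage.transform import resize as _sk_resize

from .audio import AudioSegment

__all__ = [
    "StftParams",
    "Spectrogram",
    "DetectionParams",
    "SpectrogramImage",
    "compute_spectrogram",
    "detect_calls",
    "render_fixed_image",
    "write_image_png",
    "write_images_npz",
    "IMAGE_SHAPE",
]

#: Default fixed shape (rows, columns) of rendered spectrogram images.
IMAGE_SHAPE = (192, 834)

_DB_FLOOR = -140.0  # clamp for log of zero magnitude


@dataclass(frozen=True)
class StftParams:
    """Short-time Fourier transform settings.

    ``overlap_fraction`` 0.75 with ``fft_length`` 512 gives a hop of 128
    samples; the window length equals the FFT length (no zero padding).
    """

    sample_rate: int = 250_000
    fft_length: int = 512
    window: str = "hamming"
    overlap_fraction: float = 0.75
    highpass_cutoff: float = 30_000.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.fft_length < 2 or self.fft_length & (self.fft_length - 1):
            raise ValueError("fft_length must be a power of two")
        if not 0 <= self.highpass_cutoff < self.sample_rate / 2:
            raise ValueError("highpass_cutoff must be below Nyquist")

    @property
    def hop(self) -> int:
        """Frame step in samples."""
        return int(round(self.fft_length * (1.0 - self.overlap_fraction)))

    @property
    def freq_resolution(self) -> float:
        """Frequency bin spacing in Hz (sample_rate / fft_length)."""
        return self.sample_rate / self.fft_length

    @property
    def time_resolution(self) -> float:
        """Frame step in seconds (hop / sample_rate)."""
        return self.hop / self.sample_rate


@dataclass
class Spectrogram:
    """dB-scaled magnitude spectrogram with axis metadata.

    ``magnitude_db`` is (frequency bins x time frames), rows ascending in
    frequency, values <= 0 with 0 dB at the recording maximum.  Bins below
    the high-pass cutoff have been removed.
    """

    magnitude_db: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    params: StftParams

    def __post_init__(self) -> None:
        if self.magnitude_db.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValueError("axis lengths do not match matrix shape")
        if np.any(np.diff(self.freq_axis) <= 0):
            raise ValueError("freq_axis must be strictly ascending")

    @property
    def n_frames(self) -> int:
        return self.magnitude_db.shape[1]

    @property
    def n_bins(self) -> int:
        return self.magnitude_db.shape[0]


@dataclass(frozen=True)
class DetectionParams:
    """Threshold/hold-time call detection settings.

    A frame is voiced when any retained bin exceeds ``threshold_db``;
    voiced runs closer than ``hold_time`` seconds are merged into one call.
    """

    threshold_db: float = -80.0
    hold_time: float = 0.010

    def __post_init__(self) -> None:
        if not self.threshold_db < 0:
            raise ValueError("threshold_db must be negative (dB re maximum)")
        if self.hold_time < 0:
            raise ValueError("hold_time must be >= 0")


@dataclass
class SpectrogramImage:
    """Fixed-size grayscale image of one call, values in [0, 1]."""

    pixels: np.ndarray
    shape: tuple[int, int] = IMAGE_SHAPE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != tuple(self.shape):
            raise ValueError(
                f"pixels must have shape {tuple(self.shape)}, got {self.pixels.shape}"
            )
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")


def compute_spectrogram(
    audio: AudioSegment, params: StftParams | None = None
) -> Spectrogram:
    """Compute the dB magnitude spectrogram of ``audio``.

    The high-pass is applied in the spectral domain by dropping rows below
    the cutoff — exact, and sufficient since downstream processing is
    entirely spectrogram-based.
    """
    params = params or StftParams(sample_rate=audio.sample_rate)
    if audio.sample_rate != params.sample_rate:
        raise ValueError(
            f"audio sample rate {audio.sample_rate} != params.sample_rate "
            f"{params.sample_rate}"
        )
    if len(audio) < params.fft_length:
        raise ValueError(
            f"audio ({len(audio)} samples) shorter than one analysis window "
            f"({params.fft_length} samples)"
        )
    noverlap = params.fft_length - params.hop
    freqs, times, mag = sps.spectrogram(
        audio.samples,
        fs=params.sample_rate,
        window=params.window,
        nperseg=params.fft_length,
        noverlap=noverlap,
        mode="magnitude",
        detrend=False,
    )
    keep = freqs >= params.highpass_cutoff
    mag = mag[keep]
    freqs = freqs[keep]
    ref = mag.max()
    if ref <= 0:
        db = np.full_like(mag, _DB_FLOOR)
    else:
        db = 20.0 * np.log10(np.maximum(mag / ref, 10.0 ** (_DB_FLOOR / 20.0)))
    return Spectrogram(
        magnitude_db=db, freq_axis=freqs, time_axis=times, params=params
    )


def detect_calls(
    spec: Spectrogram, det: DetectionParams | None = None
) -> list[tuple[int, int]]:
    """Detect calls as maximal voiced frame runs, merging short gaps.

    A frame is voiced when its maximum over retained bins exceeds the
    threshold; two voiced runs whose silent gap is shorter than the hold
    time are merged into a single call.  Returns sorted, non-overlapping
    half-open ``(start_frame, end_frame)`` intervals.
    """
    det = det or DetectionParams()
    voiced = (spec.magnitude_db > det.threshold_db).any(axis=0)
    hold_frames = det.hold_time / spec.params.time_resolution
    return merge_voiced_runs(voiced, hold_frames)


def merge_voiced_runs(
    voiced: np.ndarray, hold_frames: float
) -> list[tuple[int, int]]:
    """Maximal True-runs of ``voiced``, merging gaps shorter than ``hold_frames``."""
    voiced = np.asarray(voiced, dtype=bool)
    edges = np.flatnonzero(np.diff(np.r_[0, voiced.view(np.int8), 0]))
    runs = list(zip(edges[::2], edges[1::2]))
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and (start - merged[-1][1]) < hold_frames:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((int(start), int(stop)))
    return merged


def render_fixed_image(
    spec: Spectrogram,
    segment: tuple[int, int],
    shape: tuple[int, int] = IMAGE_SHAPE,
    mode: str = "pad-crop",
) -> SpectrogramImage:
    """Render a detected segment as a fixed-size grayscale image.

    Frequency: the retained band (high-pass cutoff to Nyquist) is mapped
    linearly onto ``shape[0]`` rows.  Time, in ``"pad-crop"`` mode: segments
    shorter than ``shape[1]`` frames are padded at the tail with the segment
    floor value, longer ones are center-cropped; in ``"resize"`` mode the
    segment is rescaled to the target width.  Pixel values are min-max
    scaled to [0, 1] per image (a constant segment maps to all zeros).
    """
    start, stop = segment
    if not (0 <= start < stop <= spec.n_frames):
        raise ValueError(
            f"segment {segment} out of bounds for {spec.n_frames} frames"
        )
    block = spec.magnitude_db[:, start:stop]
    n_rows, n_cols = shape

    # frequency axis: linear interpolation onto n_rows target frequencies
    # (bins are uniformly spaced, so this is a weighted two-row blend)
    if spec.freq_axis.size != n_rows:
        lo = spec.params.highpass_cutoff
        hi = spec.params.sample_rate / 2
        target_freqs = np.linspace(lo, hi, n_rows)
        df = spec.freq_axis[1] - spec.freq_axis[0]
        pos = np.clip((target_freqs - spec.freq_axis[0]) / df, 0, spec.n_bins - 1)
        i0 = np.minimum(pos.astype(int), spec.n_bins - 2)
        w = (pos - i0)[:, None]
        block = (1.0 - w) * block[i0] + w * block[i0 + 1]
    else:
        block = block.copy()

    if mode == "resize":
        block = _sk_resize(
            block, (n_rows, n_cols), order=1, mode="edge",
            anti_aliasing=block.shape[1] > n_cols, preserve_range=True,
        )
    elif mode == "pad-crop":
        width = block.shape[1]
        if width > n_cols:
            off = (width - n_cols) // 2
            block = block[:, off : off + n_cols]
        elif width < n_cols:
            pad = np.full((n_rows, n_cols - width), block.min())
            block = np.hstack([block, pad])
    else:
        raise ValueError(f"mode must be 'pad-crop' or 'resize', got {mode!r}")

    lo_v, hi_v = block.min(), block.max()
    if hi_v > lo_v:
        pixels = (block - lo_v) / (hi_v - lo_v)
    else:
        pixels = np.zeros_like(block)
    return SpectrogramImage(pixels=pixels, shape=(n_rows, n_cols))


def write_image_png(image: SpectrogramImage, path) -> None:
    """Write a rendered image as 8-bit grayscale PNG (0 -> black)."""
    from PIL import Image

    arr = np.round(image.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def write_images_npz(images: np.ndarray, path, labels=None) -> None:
    """Write a stack of rendered images (n, rows, cols) as compressed NPZ."""
    payload = {"images": np.asarray(images, dtype=np.float32)}
    if labels is not None:
        payload["labels"] = np.asarray(labels)
    np.savez_compressed(str(path), **payload)
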