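"""The 20 "standard" acoustic features of a call, plus standardization.

The feature set follows the Avisoft convention: per-frame *peak frequency*
(frequency of maximal spectral magnitude) and *peak amplitude* (that
magnitude, in dB) are tracked across the call and summarized in several
configurations.  "start"/"end" are the track values at the first and last
voiced frame; "entire" statistics run over every frame between start and
end; plain max/mean statistics run over voiced frames only (frames whose
maximum bin exceeds the detection threshold) — the voiced/entire split is
this package's reading of the two summary families, documented here because
the convention itself leaves it open.

Quartile features (quart 50/75) are the frequencies below which 50%/75% of
the first voiced frame's spectral *energy* lies, interpolated linearly
between bins.  Peak-to-peak is the range of the time-domain waveform.
All standard deviations are population (ddof=0) values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler

from .audio import AudioSegment
from .spectro import (
    IMAGE_SHAPE,
    DetectionParams,
    Spectrogram,
    StftParams,
    compute_spectrogram,
    render_fixed_image,
)

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "peak_tracks",
    "extract_features",
    "extract_feature_table",
    "call_spectrogram",
    "render_call_images",
    "read_feature_table",
    "FeatureStandardizer",
    "fit_standardizer",
    "apply_standardizer",
]

#: Canonical feature order; fixed everywhere (tables, model inputs).
FEATURE_NAMES: tuple[str, ...] = (
    "duration_ms",
    "peak_to_peak",
    "quart50_start",
    "quart75_start",
    "peak_freq_start",
    "peak_amp_start",
    "peak_freq_end",
    "peak_amp_end",
    "peak_freq_max",
    "peak_amp_max",
    "peak_freq_mean",
    "peak_amp_mean",
    "peak_freq_min_entire",
    "peak_freq_max_entire",
    "peak_amp_max_entire",
    "peak_freq_mean_entire",
    "peak_amp_mean_entire",
    "peak_freq_sd_entire",
    "peak_amp_sd_entire",
    "max_freq_sd_entire",
)


@dataclass
class FeatureVector:
    """The 20 standard features of one call, in canonical order."""

    duration_ms: float
    peak_to_peak: float
    quart50_start: float
    quart75_start: float
    peak_freq_start: float
    peak_amp_start: float
    peak_freq_end: float
    peak_amp_end: float
    peak_freq_max: float
    peak_amp_max: float
    peak_freq_mean: float
    peak_amp_mean: float
    peak_freq_min_entire: float
    peak_freq_max_entire: float
    peak_amp_max_entire: float
    peak_freq_mean_entire: float
    peak_amp_mean_entire: float
    peak_freq_sd_entire: float
    peak_amp_sd_entire: float
    max_freq_sd_entire: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])

    @classmethod
    def from_array(cls, values: np.ndarray) -> "FeatureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} values")
        return cls(**dict(zip(FEATURE_NAMES, values)))


assert tuple(f.name for f in dc_fields(FeatureVector)) == FEATURE_NAMES


def peak_tracks(
    spec: Spectrogram, segment: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (peak frequency in Hz, peak amplitude in dB) over a segment."""
    start, stop = segment
    if not (0 <= start < stop <= spec.n_frames):
        raise ValueError(f"segment {segment} out of bounds")
    block = spec.magnitude_db[:, start:stop]
    idx = block.argmax(axis=0)
    return spec.freq_axis[idx], block.max(axis=0)


def _energy_quantile_freq(
    energy: np.ndarray, freq_axis: np.ndarray, frac: float
) -> float:
    """Frequency below which ``frac`` of the spectral energy lies."""
    c = np.cumsum(energy)
    return float(np.interp(frac * c[-1], c, freq_axis))


def extract_features(
    spec: Spectrogram,
    segment: tuple[int, int],
    det: DetectionParams | None = None,
    audio: AudioSegment | None = None,
) -> FeatureVector:
    """Compute the 20 standard features of one detected segment.

    ``audio`` supplies the time-domain waveform for peak-to-peak (the range
    of the raw samples spanned by the call); without it, the range of the
    segment's linear spectral magnitude is used as a stand-in.
    Raises ``ValueError`` on an empty or entirely sub-threshold segment.
    """
    det = det or DetectionParams()
    start, stop = segment
    if not (0 <= start < stop <= spec.n_frames):
        raise ValueError(f"segment {segment} out of bounds")

    frame_max = spec.magnitude_db[:, start:stop].max(axis=0)
    voiced_rel = np.flatnonzero(frame_max > det.threshold_db)
    if voiced_rel.size == 0:
        raise ValueError("segment contains no voiced frames above threshold")
    first = start + int(voiced_rel[0])
    last = start + int(voiced_rel[-1])

    # "entire" region: every frame between start and end of the call
    pf, pa = peak_tracks(spec, (first, last + 1))
    region_max = spec.magnitude_db[:, first : last + 1].max(axis=0)
    voiced = region_max > det.threshold_db

    n_frames = last - first + 1
    duration_ms = n_frames * spec.params.time_resolution * 1e3

    if audio is not None:
        hop = spec.params.hop
        s0 = first * hop
        s1 = min(last * hop + spec.params.fft_length, len(audio))
        chunk = audio.samples[s0:s1]
        peak_to_peak = float(chunk.max() - chunk.min())
    else:
        lin = 10.0 ** (spec.magnitude_db[:, first : last + 1] / 20.0)
        peak_to_peak = float(lin.max() - lin.min())

    # energy quartiles of the first voiced frame's spectrum
    first_spectrum = 10.0 ** (spec.magnitude_db[:, first] / 20.0)
    energy = first_spectrum**2
    quart50 = _energy_quantile_freq(energy, spec.freq_axis, 0.50)
    quart75 = _energy_quantile_freq(energy, spec.freq_axis, 0.75)

    # highest supra-threshold frequency per voiced frame
    above = spec.magnitude_db[:, first : last + 1] > det.threshold_db
    max_freq = np.array(
        [
            spec.freq_axis[np.flatnonzero(col)[-1]]
            for col in above.T[voiced]
        ]
    )

    pf_v, pa_v = pf[voiced], pa[voiced]
    return FeatureVector(
        duration_ms=float(duration_ms),
        peak_to_peak=peak_to_peak,
        quart50_start=quart50,
        quart75_start=quart75,
        peak_freq_start=float(pf[0]),
        peak_amp_start=float(pa[0]),
        peak_freq_end=float(pf[-1]),
        peak_amp_end=float(pa[-1]),
        peak_freq_max=float(pf_v.max()),
        peak_amp_max=float(pa_v.max()),
        peak_freq_mean=float(pf_v.mean()),
        peak_amp_mean=float(pa_v.mean()),
        peak_freq_min_entire=float(pf.min()),
        peak_freq_max_entire=float(pf.max()),
        peak_amp_max_entire=float(pa.max()),
        peak_freq_mean_entire=float(pf.mean()),
        peak_amp_mean_entire=float(pa.mean()),
        peak_freq_sd_entire=float(pf.std()),
        peak_amp_sd_entire=float(pa.std()),
        max_freq_sd_entire=float(max_freq.std()),
    )


def call_spectrogram(
    call: AudioSegment, params: StftParams | None = None
) -> Spectrogram:
    """Spectrogram of one call, zero-padding the tail of very short calls
    so that at least one full analysis window fits."""
    params = params or StftParams(sample_rate=call.sample_rate)
    x = call.samples
    if x.size < params.fft_length:
        x = np.pad(x, (0, params.fft_length - x.size))
        call = AudioSegment(
            samples=x, sample_rate=call.sample_rate,
            label=call.label, strain=call.strain,
        )
    return compute_spectrogram(call, params)


def extract_feature_table(
    calls: list[AudioSegment],
    params: StftParams | None = None,
    det: DetectionParams | None = None,
) -> pd.DataFrame:
    """Feature table for a list of calls: 20 feature columns plus ``class``
    and ``strain`` where the calls carry labels."""
    rows = []
    for call in calls:
        spec = call_spectrogram(call, params)
        fv = extract_features(spec, (0, spec.n_frames), det, audio=call)
        row = dict(zip(FEATURE_NAMES, fv.as_array()))
        row["class"] = call.label
        row["strain"] = call.strain
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["class", "strain"])


def render_call_images(
    calls: list[AudioSegment],
    shape: tuple[int, int] = IMAGE_SHAPE,
    mode: str = "pad-crop",
    params: StftParams | None = None,
    window_frames: int = 834,
) -> np.ndarray:
    """Fixed-size spectrogram images (n, rows, cols) for a list of calls.

    Modes "pad-crop" and "resize" render directly at ``shape``.  Mode
    "downscale" renders a full-resolution ``window_frames``-wide pad-crop
    image first and then max-pools it down to ``shape`` (block reduction
    with max): relative call durations stay visible (no per-call
    stretching) and thin spectral lines and sharp step edges survive the
    reduction, unlike with averaging filters.  This is the representation
    used for reduced-scale CNN runs; block factors must divide the full
    image dimensions.
    """
    from skimage.measure import block_reduce

    images = np.empty((len(calls), *shape), dtype=np.float32)
    if mode == "downscale":
        fh, fw = IMAGE_SHAPE[0] // shape[0], window_frames // shape[1]
        if shape[0] * fh != IMAGE_SHAPE[0] or shape[1] * fw != window_frames:
            raise ValueError(
                f"target {shape} must evenly divide "
                f"({IMAGE_SHAPE[0]}, {window_frames})"
            )
    for i, call in enumerate(calls):
        spec = call_spectrogram(call, params)
        if mode == "downscale":
            full = render_fixed_image(
                spec, (0, spec.n_frames), (IMAGE_SHAPE[0], window_frames),
                "pad-crop",
            )
            images[i] = block_reduce(full.pixels, (fh, fw), np.max)
        else:
            img = render_fixed_image(spec, (0, spec.n_frames), shape, mode)
            images[i] = img.pixels
    return images


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature CSV written by :func:`extract_feature_table`,
    validating the canonical column layout."""
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table misses columns: {missing}")
    return table


class FeatureStandardizer(StandardScaler):
    """Zero-mean/unit-variance scaler fitted on training data only.

    Uses population standard deviation; constant columns keep scale 1 so
    they transform to exact zeros.  Requires at least two training rows.
    """

    def fit(self, X, y=None, sample_weight=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("standardizer requires a 2-D matrix with >= 2 rows")
        return super().fit(X, y, sample_weight=sample_weight)


def fit_standardizer(train_matrix: np.ndarray) -> FeatureStandardizer:
    """Fit a standardizer on the training matrix."""
    return FeatureStandardizer().fit(train_matrix)


def apply_standardizer(
    standardizer: FeatureStandardizer, matrix: np.ndarray
) -> np.ndarray:
    """Transform ``matrix`` with training statistics only."""
    return standardizer.transform(np.asarray(matrix, dtype=float))
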