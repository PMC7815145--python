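"""Parametric simulator of mouse-pup ultrasonic vocalizations.

Real USV recordings of this kind are rarely deposited, so the simulator
produces labeled calls of the ten Scattoni-style call categories —
complex, harmonics, two syllable, upward, downward, chevron, short,
composite, frequency steps and flat — as frequency-modulated tones whose
spectrogram contours realize each category's defining shape.  Class
imbalance and a two-genotype (WT/KO) population structure are configurable,
with the genotypes differing only in their class-frequency mix.

Category shapes are enforced at the trajectory level:

* ``flat`` — constant frequency (within a small tolerance),
* ``upward`` / ``downward`` — monotone sweeps spanning at least the
  configured minimum range,
* ``chevron`` — a single rise-then-fall arch,
* ``complex`` — at least two direction changes of the contour,
* ``frequency_steps`` — piecewise-constant with instantaneous jumps,
* ``two_syllable`` — two voiced components separated by a silent gap,
* ``short`` — total voiced span below a duration threshold,
* ``harmonics`` — fundamental plus an overtone at twice its frequency,
* ``composite`` — two simultaneous, harmonically unrelated tones.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import DEFAULT_SAMPLE_RATE, AudioSegment, write_wav

__all__ = [
    "CallClass",
    "CLASS_NAMES",
    "ShapeThresholds",
    "CallSpec",
    "Trajectory",
    "DatasetProfile",
    "CallSampler",
    "Dataset",
    "frequency_trajectory",
    "synthesize_call",
    "generate_dataset",
    "imbalanced_profile",
    "balanced_profile",
    "WT_CLASS_MIX",
    "KO_CLASS_MIX",
]


class CallClass(str, enum.Enum):
    """The ten call categories; member order defines label indices 0-9."""

    COMPLEX = "complex"
    HARMONICS = "harmonics"
    TWO_SYLLABLE = "two_syllable"
    UPWARD = "upward"
    DOWNWARD = "downward"
    CHEVRON = "chevron"
    SHORT = "short"
    COMPOSITE = "composite"
    FREQUENCY_STEPS = "frequency_steps"
    FLAT = "flat"

    @property
    def index(self) -> int:
        return CLASS_NAMES.index(self.value)


CLASS_NAMES: tuple[str, ...] = tuple(c.value for c in CallClass)


@dataclass(frozen=True)
class ShapeThresholds:
    """Contour thresholds separating the call categories.

    The taxonomy is defined by spectrogram shape; published class
    definitions give silhouettes rather than numeric cut-offs, so these
    defaults are conventional values and all are overridable.

    Attributes
    ----------
    flat_tolerance : float
        Maximum frequency excursion (Hz) still counted as "flat" (±3 kHz).
    short_max_duration : float
        Maximum voiced span (s) of a "short" call (5 ms).
    step_min_jump : float
        Minimum instantaneous jump (Hz) of a frequency step (10 kHz).
    sweep_min_range : float
        Minimum net frequency change (Hz) of an upward/downward sweep.
    """

    flat_tolerance: float = 3_000.0
    short_max_duration: float = 0.005
    step_min_jump: float = 10_000.0
    sweep_min_range: float = 12_500.0


DEFAULT_THRESHOLDS = ShapeThresholds()

#: Relative amplitude of the first overtone of a ``harmonics`` call (-6 dB).
HARMONIC_OVERTONE_GAIN = 0.5
#: Frequency ratio of the second component of a ``composite`` call
#: (harmonically unrelated to the fundamental).
COMPOSITE_RATIO = 1.4
#: Lowest admissible fundamental (Hz); the analysis high-pass sits at 30 kHz.
MIN_BASE_FREQUENCY = 30_000.0
NYQUIST = DEFAULT_SAMPLE_RATE / 2


@dataclass
class CallSpec:
    """Parameters of one synthetic call.

    ``component_gap`` applies to ``two_syllable`` calls, ``n_steps`` to
    ``frequency_steps`` and ``n_direction_changes`` to ``complex``;
    they are ignored elsewhere.
    """

    call_class: CallClass
    duration: float = 0.05
    base_frequency: float = 60_000.0
    modulation_depth: float = 0.0
    amplitude: float = 0.7
    snr_db: float = math.inf
    component_gap: float | None = None
    n_steps: int | None = None
    n_direction_changes: int | None = None

    def __post_init__(self) -> None:
        self.call_class = CallClass(self.call_class)

    def validate(self, thresholds: ShapeThresholds = DEFAULT_THRESHOLDS) -> None:
        """Raise ``ValueError`` naming the violated field, if any."""
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not self.base_frequency > MIN_BASE_FREQUENCY:
            raise ValueError(
                f"base_frequency must exceed {MIN_BASE_FREQUENCY:.0f} Hz, "
                f"got {self.base_frequency}"
            )
        if self.modulation_depth < 0:
            raise ValueError(
                f"modulation_depth must be >= 0, got {self.modulation_depth}"
            )
        if self.base_frequency + self.modulation_depth >= NYQUIST:
            raise ValueError(
                "base_frequency + modulation_depth must stay below the "
                f"{NYQUIST:.0f} Hz Nyquist limit"
            )
        if not 0 < self.amplitude <= 1:
            raise ValueError(f"amplitude must be in (0, 1], got {self.amplitude}")
        if math.isnan(self.snr_db) or self.snr_db == -math.inf:
            raise ValueError(f"snr_db must be finite or +inf, got {self.snr_db}")
        cc = self.call_class
        if cc is CallClass.SHORT and self.duration > thresholds.short_max_duration:
            raise ValueError(
                f"duration of a short call must be <= "
                f"{thresholds.short_max_duration} s, got {self.duration}"
            )
        if cc is CallClass.TWO_SYLLABLE:
            if self.component_gap is None or not 0 < self.component_gap < self.duration:
                raise ValueError(
                    "component_gap must be in (0, duration) for two_syllable, "
                    f"got {self.component_gap}"
                )
        if cc is CallClass.FREQUENCY_STEPS:
            if self.n_steps is None or self.n_steps < 1:
                raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
            if self.modulation_depth < thresholds.step_min_jump:
                raise ValueError(
                    "modulation_depth must be >= step_min_jump "
                    f"({thresholds.step_min_jump} Hz) for frequency_steps"
                )
        if cc is CallClass.COMPLEX:
            if self.n_direction_changes is None or self.n_direction_changes < 2:
                raise ValueError(
                    f"n_direction_changes must be >= 2, got {self.n_direction_changes}"
                )
        if cc in (CallClass.UPWARD, CallClass.DOWNWARD):
            if self.modulation_depth < thresholds.sweep_min_range:
                raise ValueError(
                    "modulation_depth must be >= sweep_min_range "
                    f"({thresholds.sweep_min_range} Hz) for {cc.value}"
                )


@dataclass
class Trajectory:
    """Instantaneous-frequency contour of a call.

    ``frequencies`` holds one row per tonal component (row 0 is the
    fundamental); most categories have a single component, ``harmonics``
    and ``composite`` have two.  ``voiced`` marks frames carrying signal
    (False inside the silent gap of a two-syllable call).
    """

    frequencies: np.ndarray  # (n_components, n_frames)
    voiced: np.ndarray  # (n_frames,) bool
    amplitudes: np.ndarray  # (n_components,) linear, relative to fundamental

    @property
    def fundamental(self) -> np.ndarray:
        return self.frequencies[0]

    @property
    def n_components(self) -> int:
        return self.frequencies.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frequencies.shape[1]


def frequency_trajectory(
    spec: CallSpec,
    n_frames: int,
    thresholds: ShapeThresholds = DEFAULT_THRESHOLDS,
) -> Trajectory:
    """Sample the frequency contour of ``spec`` on ``n_frames`` frames.

    The contour realizes the category's defining shape exactly (see module
    docstring); with infinite SNR the generating class is recoverable from
    the returned trajectory by shape rules alone.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    spec.validate(thresholds)

    f0 = spec.base_frequency
    depth = spec.modulation_depth
    t = np.linspace(0.0, 1.0, n_frames)
    voiced = np.ones(n_frames, dtype=bool)
    amps = np.array([1.0])
    cc = spec.call_class

    if cc in (CallClass.FLAT, CallClass.SHORT):
        freq = np.full(n_frames, f0)
    elif cc is CallClass.UPWARD:
        freq = f0 + depth * t
    elif cc is CallClass.DOWNWARD:
        freq = f0 + depth * (1.0 - t)
    elif cc is CallClass.CHEVRON:
        freq = f0 + depth * np.sin(np.pi * t)
    elif cc is CallClass.COMPLEX:
        # d interior extrema of the contour => d sign changes of the
        # frame-to-frame difference (for a sufficiently fine frame grid)
        d = int(spec.n_direction_changes)
        freq = f0 + 0.5 * depth * (1.0 + np.sin(np.pi * d * t))
    elif cc is CallClass.FREQUENCY_STEPS:
        n_seg = int(spec.n_steps) + 1
        seg = np.minimum((t * n_seg).astype(int), n_seg - 1)
        levels = np.where(np.arange(n_seg) % 2 == 0, f0, f0 + depth)
        freq = levels[seg]
    elif cc is CallClass.TWO_SYLLABLE:
        gap_frames = max(1, round(spec.component_gap / spec.duration * n_frames))
        gap_frames = min(gap_frames, max(1, n_frames - 2))
        syl = (n_frames - gap_frames) // 2
        syl1 = max(1, syl)
        syl2 = max(1, n_frames - gap_frames - syl1)
        gap_frames = n_frames - syl1 - syl2
        freq = np.full(n_frames, f0)
        if syl2 > 1 and depth > 0:  # second syllable sweeps upward
            freq[syl1 + gap_frames :] = f0 + depth * np.linspace(0, 1, syl2)
        voiced[syl1 : syl1 + gap_frames] = False
    elif cc is CallClass.HARMONICS:
        fund = np.full(n_frames, f0)
        freq = np.vstack([fund, 2.0 * fund])
        amps = np.array([1.0, HARMONIC_OVERTONE_GAIN])
    elif cc is CallClass.COMPOSITE:
        comp1 = np.full(n_frames, f0)
        freq = np.vstack([comp1, COMPOSITE_RATIO * comp1])
        amps = np.array([1.0, 0.8])
    else:  # pragma: no cover
        raise ValueError(f"unknown call class {cc}")

    freq = np.atleast_2d(freq)
    return Trajectory(frequencies=freq, voiced=voiced, amplitudes=amps)


def _voiced_envelope(voiced: np.ndarray, sample_rate: int) -> np.ndarray:
    """Amplitude envelope: 1 on voiced runs, with short raised-cosine edges."""
    env = np.zeros(voiced.size)
    ramp_max = max(2, int(0.0005 * sample_rate))  # 0.5 ms edge
    idx = np.flatnonzero(np.diff(np.r_[0, voiced.view(np.int8), 0]))
    for start, stop in zip(idx[::2], idx[1::2]):
        run = stop - start
        ramp = min(ramp_max, run // 4) or 1
        shape = np.ones(run)
        edge = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
        shape[:ramp] = edge
        shape[run - ramp :] = edge[::-1]
        env[start:stop] = shape
    return env


def synthesize_call(
    spec: CallSpec,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    rng_seed: int = 0,
    thresholds: ShapeThresholds = DEFAULT_THRESHOLDS,
) -> AudioSegment:
    """Render ``spec`` as a phase-continuous FM waveform plus white noise.

    The waveform is deterministic given ``rng_seed``.  An infinite
    ``spec.snr_db`` yields a noiseless tone.
    """
    n = round(spec.duration * sample_rate)
    if n < 1:
        raise ValueError("duration too short for one sample")
    traj = frequency_trajectory(spec, n, thresholds)
    if 2.0 * float(traj.frequencies.max()) >= sample_rate:
        raise ValueError(
            f"trajectory reaches {traj.frequencies.max():.0f} Hz, above the "
            f"{sample_rate / 2:.0f} Hz Nyquist limit"
        )

    env = _voiced_envelope(traj.voiced, sample_rate)
    x = np.zeros(n)
    for comp, amp in zip(traj.frequencies, traj.amplitudes):
        phase = 2.0 * np.pi * np.cumsum(comp) / sample_rate
        x += amp * np.sin(phase)
    x *= env
    peak = np.abs(x).max()
    if peak > 0:
        x *= spec.amplitude / peak

    if math.isfinite(spec.snr_db):
        rng = np.random.default_rng(rng_seed)
        sig_power = float(np.mean(x**2))
        noise_power = sig_power / 10.0 ** (spec.snr_db / 10.0)
        x = x + rng.normal(0.0, math.sqrt(noise_power), n)

    return AudioSegment(
        samples=x,
        sample_rate=sample_rate,
        label=spec.call_class.value,
        meta={"spec": spec},
    )


# ---------------------------------------------------------------------------
# population structure and dataset generation
# ---------------------------------------------------------------------------

#: Class-frequency mixes of the two genotypes.  The two genotypes differ only
#: in these proportions; acoustic parameters are drawn identically.  The
#: pooled (mixed) proportions anchor the minority (upward, ~2.5%) and majority
#: (frequency steps, ~24.9%) classes of a strongly imbalanced pup repertoire.
WT_CLASS_MIX: dict[str, float] = {
    "complex": 0.0850,
    "harmonics": 0.0750,
    "two_syllable": 0.0800,
    "upward": 0.0292,
    "downward": 0.0950,
    "chevron": 0.0850,
    "short": 0.1600,
    "composite": 0.0750,
    "frequency_steps": 0.2134,
    "flat": 0.1024,
}
KO_CLASS_MIX: dict[str, float] = {
    "complex": 0.0750,
    "harmonics": 0.0450,
    "two_syllable": 0.0600,
    "upward": 0.0200,
    "downward": 0.0850,
    "chevron": 0.0750,
    "short": 0.2000,
    "composite": 0.0650,
    "frequency_steps": 0.2850,
    "flat": 0.0900,
}


@dataclass
class DatasetProfile:
    """How many calls of each class to generate, for which genotype."""

    counts: dict[CallClass, int]
    strain: str = "mixed"  # "WT", "KO" or "mixed"
    seed: int = 0

    def __post_init__(self) -> None:
        self.counts = {CallClass(k): int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("all class counts must be >= 0")
        if self.strain not in ("WT", "KO", "mixed"):
            raise ValueError(f"strain must be WT, KO or mixed, got {self.strain}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _counts_from_mix(mix: dict[str, float], total: int) -> dict[CallClass, int]:
    """Largest-remainder apportionment of ``total`` over ``mix``."""
    weights = np.array([mix[c] for c in CLASS_NAMES], dtype=float)
    weights = weights / weights.sum()
    raw = weights * total
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts))
    counts[order[: total - counts.sum()]] += 1
    return {CallClass(c): int(n) for c, n in zip(CLASS_NAMES, counts)}


def imbalanced_profile(
    total: int, strain: str = "mixed", seed: int = 0
) -> DatasetProfile:
    """Profile with the study-like imbalanced class mix for ``strain``."""
    if strain == "WT":
        mix = WT_CLASS_MIX
    elif strain == "KO":
        mix = KO_CLASS_MIX
    else:
        mix = {c: 0.5 * (WT_CLASS_MIX[c] + KO_CLASS_MIX[c]) for c in CLASS_NAMES}
    return DatasetProfile(counts=_counts_from_mix(mix, total), strain=strain, seed=seed)


def balanced_profile(
    per_class: int, strain: str = "mixed", seed: int = 0
) -> DatasetProfile:
    """Profile with ``per_class`` calls of every class."""
    return DatasetProfile(
        counts={c: per_class for c in CallClass}, strain=strain, seed=seed
    )


@dataclass(frozen=True)
class CallSampler:
    """Per-class parameter ranges for random call specs.

    Defaults describe pup calls between 40 and 90 kHz, 2-140 ms long,
    recorded at moderate-to-high SNR.  ``noiseless`` overrides the SNR
    range with +inf (used for shape-recoverability checks).
    """

    duration_range: tuple[float, float] = (0.030, 0.100)
    short_duration_range: tuple[float, float] = (0.002, 0.005)
    two_syllable_duration_range: tuple[float, float] = (0.060, 0.140)
    base_range: tuple[float, float] = (50_000.0, 90_000.0)
    harmonics_base_range: tuple[float, float] = (40_000.0, 58_000.0)
    sweep_depth_range: tuple[float, float] = (15_000.0, 30_000.0)
    step_depth_range: tuple[float, float] = (12_000.0, 25_000.0)
    complex_depth_range: tuple[float, float] = (12_000.0, 25_000.0)
    amplitude_range: tuple[float, float] = (0.3, 0.9)
    snr_range_db: tuple[float, float] = (20.0, 40.0)
    gap_range: tuple[float, float] = (0.010, 0.030)
    noiseless: bool = False
    thresholds: ShapeThresholds = DEFAULT_THRESHOLDS

    def sample(self, call_class: CallClass, rng: np.random.Generator) -> CallSpec:
        cc = CallClass(call_class)
        u = rng.uniform
        duration = u(*self.duration_range)
        base = u(*self.base_range)
        depth = 0.0
        gap = None
        n_steps = None
        n_dir = None
        if cc is CallClass.SHORT:
            duration = u(*self.short_duration_range)
        elif cc is CallClass.TWO_SYLLABLE:
            duration = u(*self.two_syllable_duration_range)
            gap = u(*self.gap_range)
            depth = u(8_000.0, 15_000.0)
        elif cc in (CallClass.UPWARD, CallClass.DOWNWARD, CallClass.CHEVRON):
            depth = u(*self.sweep_depth_range)
        elif cc is CallClass.COMPLEX:
            depth = u(*self.complex_depth_range)
            n_dir = int(rng.integers(2, 5))
        elif cc is CallClass.FREQUENCY_STEPS:
            depth = u(*self.step_depth_range)
            n_steps = int(rng.integers(1, 4))
        elif cc is CallClass.HARMONICS:
            base = u(*self.harmonics_base_range)
        elif cc is CallClass.COMPOSITE:
            # keep the 1.4x partner below Nyquist with margin
            base = u(self.base_range[0], 82_000.0)
        # keep the contour below Nyquist with a 5 kHz guard band
        base = min(base, NYQUIST - 5_000.0 - depth)
        snr = math.inf if self.noiseless else u(*self.snr_range_db)
        return CallSpec(
            call_class=cc,
            duration=duration,
            base_frequency=base,
            modulation_depth=depth,
            amplitude=u(*self.amplitude_range),
            snr_db=snr,
            component_gap=gap,
            n_steps=n_steps,
            n_direction_changes=n_dir,
        )


@dataclass
class Dataset:
    """Generated calls plus their segment table.

    ``table`` columns: file, start_s, end_s, class, strain — times in
    seconds, intervals half-open [start, end).
    """

    calls: list[AudioSegment]
    table: pd.DataFrame
    profile: DatasetProfile

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def labels(self) -> np.ndarray:
        return self.table["class"].to_numpy()

    def save(self, out_dir: str | Path) -> Path:
        """Write one WAV per call plus ``segments.csv``; returns the CSV path."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fname, call in zip(self.table["file"], self.calls):
            write_wav(out / fname, call)
        csv_path = out / "segments.csv"
        self.table.to_csv(csv_path, index=False)
        return csv_path


def generate_dataset(
    profile: DatasetProfile,
    sampler: CallSampler | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> Dataset:
    """Generate exactly ``profile.counts`` labeled calls.

    Per-call parameters are drawn from ``sampler`` ranges using the profile
    seed; the result (audio and table) is deterministic given the profile.
    For a "mixed" profile each call's genotype is drawn with probability
    proportional to its class's weight in the WT vs KO mixes.
    """
    sampler = sampler or CallSampler()
    rng = np.random.default_rng(profile.seed)
    calls: list[AudioSegment] = []
    rows = []
    i = 0
    for cc in CallClass:  # fixed class order => deterministic layout
        for _ in range(profile.counts.get(cc, 0)):
            spec = sampler.sample(cc, rng)
            seed_i = int(rng.integers(0, 2**31 - 1))
            call = synthesize_call(spec, sample_rate, seed_i, sampler.thresholds)
            if profile.strain == "mixed":
                p_ko = KO_CLASS_MIX[cc.value] / (
                    KO_CLASS_MIX[cc.value] + WT_CLASS_MIX[cc.value]
                )
                strain = "KO" if rng.uniform() < p_ko else "WT"
            else:
                strain = profile.strain
            call.strain = strain
            calls.append(call)
            rows.append(
                {
                    "file": f"call_{i:05d}.wav",
                    "start_s": 0.0,
                    "end_s": call.duration,
                    "class": cc.value,
                    "strain": strain,
                }
            )
            i += 1
    table = pd.DataFrame(
        rows, columns=["file", "start_s", "end_s", "class", "strain"]
    )
    return Dataset(calls=calls, table=table, profile=profile)
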