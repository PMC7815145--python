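"""Synthetic call generator: trajectory shapes, rendering, datasets."""

import numpy as np
import pytest

import squeaksort as sq
from squeaksort.synth import (
    CLASS_NAMES,
    CallClass,
    CallSampler,
    CallSpec,
    DatasetProfile,
    frequency_trajectory,
    generate_dataset,
    imbalanced_profile,
    synthesize_call,
)

from _trajectory_oracle import classify_trajectory


class TestCallClass:
    def test_exactly_ten_classes_in_fixed_order(self):
        assert CLASS_NAMES == (
            "complex", "harmonics", "two_syllable", "upward", "downward",
            "chevron", "short", "composite", "frequency_steps", "flat",
        )
        assert [c.index for c in CallClass] == list(range(10))


class TestFrequencyTrajectory:
    def test_flat_is_constant(self):
        spec = CallSpec(CallClass.FLAT, base_frequency=60_000.0)
        tr = frequency_trajectory(spec, 80)
        assert tr.fundamental.max() - tr.fundamental.min() == 0
        assert np.all(tr.fundamental == 60_000.0)

    def test_upward_spans_depth_monotonically(self):
        spec = CallSpec(
            CallClass.UPWARD, base_frequency=50_000.0, modulation_depth=20_000.0
        )
        tr = frequency_trajectory(spec, 100)
        f = tr.fundamental
        assert f[0] == pytest.approx(50_000.0)
        assert f[-1] == pytest.approx(70_000.0)
        assert np.all(np.diff(f) >= 0)

    def test_downward_mirrors_upward(self):
        spec = CallSpec(
            CallClass.DOWNWARD, base_frequency=50_000.0, modulation_depth=20_000.0
        )
        f = frequency_trajectory(spec, 100).fundamental
        assert f[0] == pytest.approx(70_000.0)
        assert f[-1] == pytest.approx(50_000.0)
        assert np.all(np.diff(f) <= 0)

    def test_chevron_single_interior_maximum(self):
        spec = CallSpec(
            CallClass.CHEVRON, base_frequency=55_000.0, modulation_depth=25_000.0
        )
        f = frequency_trajectory(spec, 101).fundamental
        assert f[0] == pytest.approx(55_000.0)
        assert f[-1] == pytest.approx(55_000.0, abs=1e-6)
        peak = f.argmax()
        assert 0 < peak < 100
        assert f[peak] == pytest.approx(80_000.0)
        assert np.all(np.diff(f[: peak + 1]) >= 0)
        assert np.all(np.diff(f[peak:]) <= 0)

    def test_complex_has_requested_direction_changes(self):
        spec = CallSpec(
            CallClass.COMPLEX,
            base_frequency=55_000.0,
            modulation_depth=20_000.0,
            n_direction_changes=3,
        )
        f = frequency_trajectory(spec, 400).fundamental
        d = np.diff(f)
        signs = np.sign(d[np.abs(d) > 1e-9])
        assert np.sum(signs[1:] != signs[:-1]) == 3

    def test_frequency_steps_piecewise_constant_jumps(self):
        spec = CallSpec(
            CallClass.FREQUENCY_STEPS,
            base_frequency=50_000.0,
            modulation_depth=15_000.0,
            n_steps=2,
        )
        f = frequency_trajectory(spec, 300).fundamental
        d = np.diff(f)
        jumps = np.abs(d[d != 0])
        assert jumps.size == 2
        assert np.all(jumps >= 10_000.0)

    def test_two_syllable_silent_gap(self):
        spec = CallSpec(
            CallClass.TWO_SYLLABLE,
            duration=0.1,
            base_frequency=55_000.0,
            modulation_depth=10_000.0,
            component_gap=0.02,
        )
        tr = frequency_trajectory(spec, 200)
        gaps = np.flatnonzero(~tr.voiced)
        assert gaps.size > 0
        assert gaps[0] > 0 and gaps[-1] < 199  # gap is interior
        assert np.all(np.diff(gaps) == 1)  # one contiguous gap

    def test_multi_component_classes(self):
        harm = frequency_trajectory(
            CallSpec(CallClass.HARMONICS, base_frequency=50_000.0), 50
        )
        assert harm.n_components == 2
        np.testing.assert_allclose(harm.frequencies[1], 2 * harm.frequencies[0])
        comp = frequency_trajectory(
            CallSpec(CallClass.COMPOSITE, base_frequency=60_000.0), 50
        )
        assert comp.n_components == 2
        ratio = comp.frequencies[1] / comp.frequencies[0]
        assert not np.allclose(ratio, 2.0, rtol=0.05)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(call_class="flat", duration=-1), "duration"),
            (dict(call_class="flat", base_frequency=20_000.0), "base_frequency"),
            (dict(call_class="short", duration=0.02), "duration"),
            (dict(call_class="upward", modulation_depth=1_000.0), "modulation_depth"),
            (dict(call_class="complex", n_direction_changes=1), "n_direction_changes"),
            (dict(call_class="frequency_steps", n_steps=0,
                  modulation_depth=15_000.0), "n_steps"),
            (dict(call_class="two_syllable", component_gap=None), "component_gap"),
            (dict(call_class="flat", base_frequency=120_000.0,
                  modulation_depth=10_000.0), "modulation_depth"),
        ],
    )
    def test_invalid_specs_name_the_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            frequency_trajectory(CallSpec(**kwargs), 10)


class TestClassRecoverability:
    @pytest.mark.parametrize("call_class", list(CallClass))
    def test_rule_oracle_recovers_generating_class(self, call_class):
        """On noiseless specs, shape rules recover the label every time."""
        sampler = CallSampler(noiseless=True)
        rng = np.random.default_rng(call_class.index)
        for _ in range(25):
            spec = sampler.sample(call_class, rng)
            n = max(50, round(spec.duration * 5000))
            tr = frequency_trajectory(spec, n)
            assert classify_trajectory(tr, spec.duration) == call_class.value


class TestSynthesizeCall:
    def test_pure_tone_length_and_fft_peak(self):
        spec = CallSpec(CallClass.FLAT, duration=0.03, base_frequency=60_000.0)
        call = synthesize_call(spec, 250_000, rng_seed=0)
        assert len(call) == 7500
        freqs = np.fft.rfftfreq(len(call), 1 / 250_000)
        peak = freqs[np.abs(np.fft.rfft(call.samples)).argmax()]
        assert peak == pytest.approx(60_000.0, abs=freqs[1])

    def test_short_call_voiced_span(self):
        spec = CallSpec(CallClass.SHORT, duration=0.004, base_frequency=65_000.0)
        call = synthesize_call(spec, 250_000, rng_seed=1)
        assert len(call) / call.sample_rate <= 0.005

    def test_determinism_same_seed(self):
        spec = CallSpec(
            CallClass.UPWARD, base_frequency=50_000.0,
            modulation_depth=20_000.0, snr_db=20.0,
        )
        a = synthesize_call(spec, 250_000, rng_seed=5)
        b = synthesize_call(spec, 250_000, rng_seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_nyquist_violation_raises(self):
        spec = CallSpec(CallClass.HARMONICS, base_frequency=70_000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            synthesize_call(spec, 250_000)  # overtone at 140 kHz

    def test_amplitude_scaling(self):
        spec = CallSpec(CallClass.FLAT, base_frequency=60_000.0, amplitude=0.5)
        call = synthesize_call(spec, 250_000)
        assert np.abs(call.samples).max() == pytest.approx(0.5)


class TestSpectralConfinement:
    def test_energy_above_highpass(self, small_dataset):
        """>=95% of every call's energy sits above the 30 kHz high-pass."""
        for call in small_dataset.calls[::7]:
            spectrum = np.abs(np.fft.rfft(call.samples)) ** 2
            freqs = np.fft.rfftfreq(len(call), 1 / call.sample_rate)
            frac = spectrum[freqs >= 30_000].sum() / spectrum.sum()
            assert frac >= 0.95


class TestGenerateDataset:
    def test_exact_counts_for_imbalanced_profile(self):
        profile = DatasetProfile(
            counts={"upward": 30, "frequency_steps": 55}, strain="WT", seed=0
        )
        ds = generate_dataset(profile)
        hist = ds.table["class"].value_counts().to_dict()
        assert hist == {"frequency_steps": 55, "upward": 30}
        assert len(ds) == 85
        assert set(ds.table["strain"]) == {"WT"}

    def test_empty_profile_gives_empty_dataset(self):
        ds = generate_dataset(DatasetProfile(counts={}, seed=0))
        assert len(ds) == 0
        assert len(ds.table) == 0

    def test_determinism_same_profile(self):
        p = sq.balanced_profile(5, seed=1)
        a = generate_dataset(p)
        b = generate_dataset(p)
        assert a.table.equals(b.table)
        for ca, cb in zip(a.calls, b.calls):
            np.testing.assert_array_equal(ca.samples, cb.samples)

    def test_imbalanced_profile_totals_and_anchors(self):
        prof = imbalanced_profile(48_699, "mixed")
        assert prof.total == 48_699
        assert prof.counts[CallClass.UPWARD] == min(prof.counts.values())
        assert prof.counts[CallClass.FREQUENCY_STEPS] == max(prof.counts.values())

    def test_strain_mixes_differ(self):
        wt = imbalanced_profile(10_000, "WT").counts
        ko = imbalanced_profile(10_000, "KO").counts
        assert wt[CallClass.HARMONICS] > ko[CallClass.HARMONICS]
        assert wt[CallClass.FREQUENCY_STEPS] < ko[CallClass.FREQUENCY_STEPS]

    def test_save_roundtrip(self, tmp_path):
        ds = generate_dataset(sq.balanced_profile(2, seed=0))
        csv = ds.save(tmp_path)
        assert csv.exists()
        import pandas as pd

        table = pd.read_csv(csv)
        assert list(table.columns) == ["file", "start_s", "end_s", "class", "strain"]
        assert len(table) == 20
        reread = sq.read_wav(tmp_path / table["file"].iloc[0])
        assert reread.sample_rate == 250_000
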