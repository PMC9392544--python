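"""Preprocessing chain: filters, ICA, segmentation, labelling, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegresp import (
    ConfigurationError,
    EEGRecording,
    FilterSpec,
    RecordingSpec,
    apply_filter,
    assemble_dataset,
    generate_recording,
    label_response,
    segment,
)
from eegresp.preprocess import (
    RejectionCriteria,
    cohort_model_inputs,
    count_segments,
    reject_artifact_components,
    run_ica,
)
from eegresp.synth import ArtifactSpec


FS = 500.0


def tone(freq, duration=10.0, amp=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    data = amp * np.tile(np.sin(2 * np.pi * freq * t), (19, 1))
    return EEGRecording(data=data, sampling_rate=fs)


def rms(x):
    return np.sqrt(np.mean(x ** 2))


def trim(rec, seconds=1.0):
    n = int(seconds * rec.sampling_rate)
    return rec.data[:, n:-n]


class TestFilters:
    def test_notch_kills_50hz_tone(self):
        rec = tone(50.0)
        out = apply_filter(rec, FilterSpec(kind="notch"))
        assert rms(trim(out)) <= 0.01 * rms(trim(rec))

    def test_bandpass_removes_dc(self):
        rec = EEGRecording(data=np.full((19, 5000), 7.5), sampling_rate=FS)
        out = apply_filter(rec, FilterSpec(kind="elliptic_bandpass"))
        assert np.abs(trim(out)).max() < 0.05

    @pytest.mark.parametrize("kind", ["elliptic_bandpass", "chebyshev2_bandpass"])
    def test_10hz_preserved_in_passband(self, kind):
        rec = tone(10.0)
        out = apply_filter(rec, FilterSpec(kind=kind))
        ratio = rms(trim(out, 2.0)) / rms(trim(rec, 2.0))
        # forward-backward elliptic with 1 dB ripple: gain in [-2 dB, 0]
        assert 0.75 <= ratio <= 1.02

    def test_filtering_is_linear(self):
        rng = np.random.default_rng(0)
        x = EEGRecording(data=rng.standard_normal((19, 4000)), sampling_rate=FS)
        y = EEGRecording(data=rng.standard_normal((19, 4000)), sampling_rate=FS)
        spec = FilterSpec(kind="elliptic_bandpass")
        a, b = 2.5, -1.25
        combo = EEGRecording(data=a * x.data + b * y.data, sampling_rate=FS)
        lhs = apply_filter(combo, spec).data
        rhs = a * apply_filter(x, spec).data + b * apply_filter(y, spec).data
        assert np.allclose(lhs, rhs, atol=1e-8 * np.abs(lhs).max())

    def test_zero_phase_no_lag(self):
        # aperiodic band-limited input so the correlation peak is unique
        rng = np.random.default_rng(1)
        rec = EEGRecording(data=rng.standard_normal((19, 5000)), sampling_rate=FS)
        rec = apply_filter(rec, FilterSpec(kind="elliptic_bandpass", low_hz=5, high_hz=15))
        out = apply_filter(rec, FilterSpec(kind="elliptic_bandpass"))
        x, y = trim(rec)[0], trim(out)[0]
        lags = np.arange(-50, 51)
        xc = [np.dot(x[50 + k: len(x) - 50 + k], y[50: -50]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_bad_designs_rejected(self):
        rec = tone(10.0, duration=2.0)
        with pytest.raises(ConfigurationError):
            apply_filter(rec, FilterSpec(kind="elliptic_bandpass", high_hz=400.0))
        with pytest.raises(ConfigurationError):
            apply_filter(rec, FilterSpec(kind="notch", center_hz=300.0))
        with pytest.raises(ConfigurationError):
            FilterSpec(kind="elliptic_bandpass", order=0).design(FS)


class TestICA:
    def test_recovers_planted_independent_sources(self):
        rng = np.random.default_rng(3)
        n = 20_000
        t = np.arange(n) / FS
        sources = np.stack([
            np.sin(2 * np.pi * 7.0 * t),
            np.sign(np.sin(2 * np.pi * 3.1 * t)),
            rng.uniform(-1, 1, n),
        ])
        mixing = rng.standard_normal((19, 3))
        rec = EEGRecording(data=mixing @ sources, sampling_rate=FS)
        with pytest.warns(RuntimeWarning, match="rank"):
            ica = run_ica(rec, n_components=19, seed=0)
        assert ica.n_components == 3
        # greedy matching by absolute correlation
        remaining = list(range(3))
        for s in sources:
            corrs = [abs(np.corrcoef(s, ica.sources[j])[0, 1]) for j in remaining]
            k = int(np.argmax(corrs))
            assert corrs[k] >= 0.95
            remaining.pop(k)

    def test_empty_rejection_is_identity(self, short_recording):
        ica = run_ica(short_recording, seed=0)
        back = ica.reconstruct(short_recording)
        scale = np.abs(short_recording.data).max()
        assert np.abs(back.data - short_recording.data).max() <= 1e-6 * scale

    def test_sources_pairwise_uncorrelated(self, short_recording):
        ica = run_ica(short_recording, seed=0)
        c = np.corrcoef(ica.sources)
        off = c - np.diag(np.diag(c))
        assert np.abs(off).max() < 1e-6

    def test_seed_determinism(self, short_recording):
        a = run_ica(short_recording, seed=4)
        b = run_ica(short_recording, seed=4)
        assert np.array_equal(a.mixing, b.mixing)


class TestArtifactRejection:
    def test_blinks_flagged_and_frontal_slow_power_reduced(self, subject):
        spec = RecordingSpec(
            duration=20.0, conditions=("eyes_closed",),
            artifacts=ArtifactSpec(blink_rate=20.0, muscle_burst_rate=0,
                                   line_noise_amp=0, drift_amp=0))
        rec = generate_recording(subject, spec, seed=8)
        ica = run_ica(rec, seed=0)
        ica = reject_artifact_components(ica, rec)
        assert len(ica.rejected) >= 1
        clean = ica.reconstruct(rec)
        from scipy.signal import welch
        for ch in (0, 1):  # Fp1, Fp2
            f, p_in = welch(rec.data[ch], fs=FS, nperseg=2048)
            _, p_out = welch(clean.data[ch], fs=FS, nperseg=2048)
            slow = f < 4.0
            assert p_out[slow].sum() < p_in[slow].sum()

    def test_clean_recording_with_conservative_thresholds(self, subject):
        quiet = ArtifactSpec(blink_rate=0, muscle_burst_rate=0,
                             line_noise_amp=0, drift_amp=0)
        rec = generate_recording(
            subject, RecordingSpec(duration=10.0, conditions=("eyes_closed",),
                                   artifacts=quiet), seed=9)
        ica = run_ica(rec, seed=0)
        crit = RejectionCriteria(blink_corr_threshold=0.995, kurtosis_threshold=50.0)
        ica = reject_artifact_components(ica, rec, crit)
        assert ica.rejected == frozenset()
        back = ica.reconstruct(rec)
        assert np.abs(back.data - rec.data).max() <= 1e-6 * np.abs(rec.data).max()

    def test_infinite_thresholds_reject_nothing(self, short_recording):
        ica = run_ica(short_recording, seed=0)
        crit = RejectionCriteria(blink_corr_threshold=np.inf,
                                 kurtosis_threshold=np.inf)
        assert reject_artifact_components(ica, short_recording, crit).rejected == frozenset()


class TestSegmentation:
    def test_reference_total_segment_count(self):
        # 19 x 13,841,500 samples cut into 1 s epochs
        assert count_segments(13_841_500, 500) == 27_683
        assert count_segments(14_025_000, 500) == 28_050

    @pytest.mark.parametrize("n_samples,expected", [(1000, 2), (999, 1), (499, 0)])
    def test_floor_division(self, n_samples, expected, subject):
        rec = EEGRecording(data=np.zeros((19, n_samples)), sampling_rate=FS)
        if expected == 0:
            with pytest.warns(RuntimeWarning):
                st_ = segment(rec, 500)
        else:
            st_ = segment(rec, 500)
        assert st_.n_segments == expected
        assert st_.data.shape[1:] == (500, 19)

    def test_time_major_layout(self):
        data = np.arange(19 * 1000).reshape(19, 1000).astype(float)
        rec = EEGRecording(data=data, sampling_rate=FS, subject_id="A")
        st_ = segment(rec, 500, label=1)
        assert np.array_equal(st_.data[0][:, 3], data[3, :500])
        assert np.array_equal(st_.data[1][:, 3], data[3, 500:])
        assert list(st_.meta["source_offset"]) == [0, 500]
        assert set(st_.meta["label"]) == {1}

    @given(n_samples=st.integers(1, 5000), seg_len=st.integers(1, 800))
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, n_samples, seg_len):
        n_seg = count_segments(n_samples, seg_len)
        assert n_seg * seg_len <= n_samples < (n_seg + 1) * seg_len


class TestLabelling:
    @pytest.mark.parametrize("pre,post,expected", [
        (30, 15, "responder"),       # exactly 50%
        (30, 16, "nonresponder"),    # 46.7%
        (35, 27, "nonresponder"),    # typical nonresponder group means
        (31, 8, "responder"),        # typical responder group means
    ])
    def test_examples(self, pre, post, expected):
        assert label_response(pre, post) == expected

    def test_zero_pre_is_an_error(self):
        with pytest.raises(ConfigurationError):
            label_response(0, 0)

    @given(pre=st.integers(1, 60), post=st.integers(0, 60), k=st.integers(1, 20))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, pre, post, k):
        assert label_response(pre, post) == label_response(k * pre, k * post)


class TestAssembly:
    def test_model_definitions(self, tiny_cohort):
        pairs = list(cohort_model_inputs(tiny_cohort, 5))

        m1 = assemble_dataset(pairs, 1)
        # female pre-vs-post: every subject contributes segments to BOTH classes
        for sid in np.unique(m1.subject_ids):
            assert set(m1.meta.loc[m1.meta.subject_id == sid, "label"]) == {0, 1}
        sexes = {p.subject_id: p.sex for p, _ in pairs}
        assert all(sexes[s] == "female" for s in m1.subject_ids)

        m3 = assemble_dataset(pairs, 3)
        assert all(sexes[s] == "female" for s in m3.subject_ids)
        assert set(m3.meta["session"]) == {"pre"}
        assert set(m3.labels) == {0, 1}

        m5 = assemble_dataset(pairs, 5)
        assert set(sexes[s] for s in m5.subject_ids) == {"female", "male"}
        assert set(m5.meta["session"]) == {"pre"}
        assert set(m5.meta["condition"]) == {"eyes_open", "eyes_closed"}

    def test_bad_model_id(self, tiny_cohort):
        pairs = list(cohort_model_inputs(tiny_cohort, 5))
        with pytest.raises(ConfigurationError):
            assemble_dataset(pairs, 6)

    def test_single_class_is_an_error(self, tiny_cohort):
        # keep only nonresponder females: model 3 cannot form two classes
        pairs = [(p, r) for p, r in cohort_model_inputs(tiny_cohort, 3)
                 if p.sex == "female" and not p.is_responder]
        with pytest.raises(ConfigurationError):
            assemble_dataset(pairs, 3)
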