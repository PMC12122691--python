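import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from predann.preprocessing import (
    AudioStimulus,
    EEGRecording,
    SplitSpec,
    apply_delay,
    clamp_values,
    extract_windows,
    resample_recording,
    robust_scale_channels,
    stratified_split,
    truncate_and_excerpt,
)


def make_rec(data, fs=125.0, **kw):
    return EEGRecording(data=np.asarray(data, dtype=float), fs=fs, **kw)


class TestRobustScale:
    def test_hand_computed_median_iqr(self):
        out = robust_scale_channels(make_rec([[0.0, 10.0, 20.0]]))
        np.testing.assert_allclose(out.data, [[-1.0, 0.0, 1.0]])

    def test_constant_channel_centered_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero IQR"):
            out = robust_scale_channels(make_rec([[5.0, 5.0, 5.0], [0.0, 1.0, 2.0]]))
        np.testing.assert_allclose(out.data[0], 0.0)

    def test_idempotent_on_normalized_input(self):
        rng = np.random.default_rng(0)
        rec = robust_scale_channels(make_rec(rng.standard_normal((4, 500))))
        again = robust_scale_channels(rec)
        np.testing.assert_allclose(again.data, rec.data, atol=1e-12)

    def test_output_median_zero_iqr_one(self, rng):
        out = robust_scale_channels(make_rec(rng.standard_normal((8, 1000)) * 40 + 3))
        med = np.median(out.data, axis=1)
        q1, q3 = np.percentile(out.data, [25, 75], axis=1)
        np.testing.assert_allclose(med, 0.0, atol=1e-9)
        np.testing.assert_allclose(q3 - q1, 1.0, atol=1e-9)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            robust_scale_channels(make_rec([[1.0]]))


class TestClamp:
    @pytest.mark.parametrize(
        "value,expected", [(25.0, 20.0), (-25.0, -20.0), (5.0, 5.0)]
    )
    def test_bound_examples(self, value, expected):
        out = clamp_values(make_rec([[value]]))
        assert out.data[0, 0] == expected

    def test_idempotent(self, rng):
        rec = make_rec(rng.standard_normal((3, 200)) * 50)
        once = clamp_values(rec)
        twice = clamp_values(once)
        np.testing.assert_array_equal(once.data, twice.data)
        assert np.all(np.abs(once.data) <= 20.0)

    def test_rejects_nonpositive_bound(self):
        with pytest.raises(ValueError):
            clamp_values(make_rec([[1.0]]), bound=0.0)


class TestExcerpting:
    def test_four_minutes_gives_eight_excerpts(self):
        rec = make_rec(np.arange(125 * 240, dtype=float)[None, :])
        parts = truncate_and_excerpt(rec, 240.0, 30.0)
        assert len(parts) == 8
        assert all(p.n_samples == 3750 for p in parts)

    def test_excerpts_concatenate_exactly(self):
        rec = make_rec(np.random.default_rng(3).standard_normal((2, 125 * 250)))
        parts = truncate_and_excerpt(rec, 240.0, 30.0)
        np.testing.assert_array_equal(
            np.concatenate([p.data for p in parts], axis=1),
            rec.data[:, : 125 * 240],
        )

    def test_single_excerpt_equals_truncated_input(self):
        rec = make_rec(np.arange(1250, dtype=float)[None, :])
        (only,) = truncate_and_excerpt(rec, 10.0, 10.0)
        np.testing.assert_array_equal(only.data, rec.data)

    def test_short_recording_error_names_deficit(self):
        with pytest.raises(ValueError, match="shorter"):
            truncate_and_excerpt(make_rec(np.zeros((1, 125 * 100))), 240.0, 30.0)


class _Excerpt:
    def __init__(self, song_id):
        self.song_id = song_id


class TestStratifiedSplit:
    def test_six_two_per_class(self):
        items = [_Excerpt(c) for c in range(5) for _ in range(8)]
        train, val = stratified_split(items, SplitSpec(train_fraction=0.75, seed=0))
        for c in range(5):
            assert sum(1 for x in train if x.song_id == c) == 6
            assert sum(1 for x in val if x.song_id == c) == 2

    def test_half_split_two_per_class(self):
        items = [_Excerpt(c) for c in range(3) for _ in range(2)]
        train, val = stratified_split(items, SplitSpec(train_fraction=0.5, seed=1))
        for c in range(3):
            assert sum(1 for x in train if x.song_id == c) == 1
            assert sum(1 for x in val if x.song_id == c) == 1

    def test_same_seed_same_assignment_union_disjoint(self):
        items = [_Excerpt(c) for c in range(4) for _ in range(6)]
        a_train, a_val = stratified_split(items, SplitSpec(seed=7))
        b_train, b_val = stratified_split(items, SplitSpec(seed=7))
        assert [id(x) for x in a_train] == [id(x) for x in b_train]
        assert set(map(id, a_train)) | set(map(id, a_val)) == set(map(id, items))
        assert set(map(id, a_train)) & set(map(id, a_val)) == set()

    def test_singleton_class_rejected(self):
        items = [_Excerpt(0), _Excerpt(0), _Excerpt(1)]
        with pytest.raises(ValueError):
            stratified_split(items, SplitSpec())


class TestApplyDelay:
    def setup_method(self):
        self.eeg = make_rec(np.arange(125 * 10, dtype=float)[None, :].repeat(2, 0))
        self.audio = AudioStimulus(np.arange(125 * 10, dtype=float), fs=125.0)

    def test_zero_delay_windows_cover_same_interval(self):
        seg = apply_delay(self.eeg, self.audio, 0.0, 3.0, 1.0)
        np.testing.assert_array_equal(seg.eeg[0], seg.audio)

    @pytest.mark.parametrize("delay_ms,shift", [(200.0, 25), (640.0, 80)])
    def test_delay_shifts_eeg_start(self, delay_ms, shift):
        seg = apply_delay(self.eeg, self.audio, delay_ms, 3.0, 1.0)
        assert seg.eeg[0, 0] == self.audio.waveform[125] + shift

    def test_window_past_end_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            apply_delay(self.eeg, self.audio, 400.0, 3.0, 7.0)


class TestExtractWindows:
    @pytest.mark.parametrize(
        "n,w,s,expected", [(3750, 375, 375, 10), (3750, 375, 200, 17)]
    )
    def test_window_counts(self, n, w, s, expected):
        rec = make_rec(np.zeros((1, n)))
        assert len(extract_windows(rec, w, s)) == expected

    def test_full_length_window(self):
        rec = make_rec(np.arange(100, dtype=float)[None, :])
        (win,) = extract_windows(rec, 100, 1)
        np.testing.assert_array_equal(win, rec.data)

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError):
            extract_windows(make_rec(np.zeros((1, 10))), 11, 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n=st.integers(10, 400),
        w=st.integers(1, 400),
        s=st.integers(1, 50),
    )
    def test_count_formula(self, n, w, s):
        if w > n:
            return
        rec = make_rec(np.zeros((1, n)))
        assert len(extract_windows(rec, w, s)) == (n - w) // s + 1


def test_polyphase_resampling_changes_rate_and_length():
    rec = make_rec(np.sin(np.arange(8000) / 50.0)[None, :], fs=1000.0)
    out = resample_recording(rec, 125.0)
    assert out.fs == 125.0
    assert out.n_samples == 1000
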