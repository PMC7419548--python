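"""Feature extraction: filter responses, spectral features, phase, artifact
rejection, and the assembled design matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endomod import (
    ArtifactSpec,
    FilterSpec,
    SpectralSpec,
    build_feature_matrices,
    compute_baseline_stats,
    encode_phase,
    extract_phase,
    extract_stbha,
    extract_stp,
    reject_artifacts,
    remove_line_noise,
)

FS = 1000.0


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


def _tone(freq, seconds=10.0, phase=0.0):
    t = np.arange(int(seconds * FS)) / FS
    return np.cos(2 * np.pi * freq * t + phase)


class TestLineNoiseFilter:
    def test_60hz_tone_is_suppressed(self):
        x = _tone(60.0, seconds=2.0)
        out = remove_line_noise(x, FilterSpec(), FS)
        mid = slice(500, 1500)
        assert _rms(out[mid]) < 0.05 * _rms(x[mid])

    def test_10hz_tone_is_preserved(self):
        x = _tone(10.0, seconds=2.0)
        out = remove_line_noise(x, FilterSpec(), FS)
        mid = slice(500, 1500)
        assert abs(_rms(out[mid]) - _rms(x[mid])) < 0.02 * _rms(x[mid])

    def test_zero_input_gives_zero_output(self):
        assert np.allclose(remove_line_noise(np.zeros(1000), FilterSpec(), FS), 0)

    def test_nonfinite_input_rejected(self):
        x = np.zeros(1000)
        x[3] = np.nan
        with pytest.raises(ValueError):
            remove_line_noise(x, FilterSpec(), FS)


class TestStp:
    # the 0.2 Hz band edge has a multi-second transient, so steady-state
    # checks use long tones and their central second

    def test_dc_offset_removed(self):
        out = extract_stp(np.full(10000, 7.0), FilterSpec(), FS)
        assert abs(out[4500:5500].mean()) < 0.07

    def test_in_band_50hz_amplitude_preserved(self):
        x = _tone(50.0)
        out = extract_stp(x, FilterSpec(), FS)
        mid = slice(4500, 5500)
        assert abs(_rms(out[mid]) - _rms(x[mid])) < 0.05 * _rms(x[mid])


class TestBaselineStats:
    def test_white_noise_baseline_has_positive_variances(self, rng):
        segs = rng.standard_normal((3, 2000))
        stats = compute_baseline_stats(segs, SpectralSpec(), FS)
        assert np.all(stats.var > 0)
        assert stats.freqs[0] == 2.0 and stats.freqs[-1] == 100.0

    def test_duplicated_segment_is_idempotent(self, rng):
        seg = rng.standard_normal((1, 2000))
        one = compute_baseline_stats(seg, SpectralSpec(), FS)
        two = compute_baseline_stats(np.vstack([seg, seg]), SpectralSpec(), FS)
        assert np.allclose(one.mean, two.mean)
        assert np.allclose(one.var, two.var)

    def test_doubling_amplitude_quadruples_psd_means(self, rng):
        seg = rng.standard_normal((2, 2000))
        base = compute_baseline_stats(seg, SpectralSpec(), FS)
        loud = compute_baseline_stats(2 * seg, SpectralSpec(), FS)
        assert np.allclose(loud.mean, 4 * base.mean, rtol=1e-10)

    def test_short_baseline_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_baseline_stats(rng.standard_normal((1, 500)),
                                   SpectralSpec(), FS)


class TestStbha:
    def test_trials_matching_baseline_have_near_zero_mean(self, rng):
        spec = SpectralSpec()
        segs = rng.standard_normal((4, 3000))
        stats = compute_baseline_stats(segs, spec, FS)
        trials = rng.standard_normal((50, 1800))
        _, stbha = extract_stbha(trials, stats, spec, FS, epoch_start_ms=-900)
        assert abs(stbha.mean()) < 0.2

    def test_injected_70hz_burst_elevates_post_onset_steps_only(self, rng):
        spec = SpectralSpec()
        stats = compute_baseline_stats(rng.standard_normal((4, 3000)), spec, FS)
        trials = rng.standard_normal((20, 1800))
        t_ms = np.arange(-900, 900)
        burst = (t_ms >= 200) & (t_ms < 300)
        trials[:, burst] += 3 * np.cos(2 * np.pi * 70 * t_ms[burst] / 1000.0)
        centers, stbha = extract_stbha(trials, stats, spec, FS, epoch_start_ms=-900)
        in_burst = (centers >= 200) & (centers < 300)
        far = centers < -200
        assert stbha[:, in_burst].mean() > 1.0
        assert abs(stbha[:, far].mean()) < 0.3

    def test_mismatched_electrode_rejected(self, rng):
        spec = SpectralSpec()
        stats = compute_baseline_stats(rng.standard_normal((1, 2000)), spec, FS,
                                       electrode_id="e001")
        with pytest.raises(ValueError):
            extract_stbha(rng.standard_normal((5, 1800)), stats, spec, FS,
                          epoch_start_ms=-900, electrode_id="e002")


class TestPhase:
    def test_bin_aligned_cosine_recovers_its_phase(self):
        tau = np.arange(400) / FS
        for phi in (-2.0, 0.3, 1.4):
            theta = extract_phase(np.cos(2 * np.pi * 15.0 * tau + phi))
            k15 = int(15.0 / 2.5) - 1
            assert abs(np.angle(np.exp(1j * (theta[k15] - phi)))) < 1e-6

    def test_output_has_60_phases_spanning_2p5_to_150hz(self, rng):
        theta = extract_phase(rng.standard_normal(400))
        assert theta.shape == (60,)
        assert np.all((theta > -np.pi - 1e-12) & (theta <= np.pi + 1e-12))

    def test_circular_shift_by_fundamental_period_preserves_phases(self, rng):
        x = rng.standard_normal(400)
        assert np.allclose(extract_phase(np.roll(x, 400)), extract_phase(x))

    def test_wrong_window_length_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_phase(rng.standard_normal(399))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-np.pi, np.pi), min_size=1, max_size=60))
    def test_phase_encoding_pairs_have_unit_norm(self, thetas):
        enc = encode_phase(np.asarray(thetas))[0]
        assert np.allclose(enc[0::2] ** 2 + enc[1::2] ** 2, 1.0)


class TestArtifactRejection:
    def test_single_extreme_spike_trial_removed(self, rng):
        trials = rng.standard_normal((100, 500))
        trials[17, 250] = 50.0
        kept = reject_artifacts(trials, ArtifactSpec(max_jump_uv=1e9))
        assert 17 not in kept
        assert kept.size == 99

    def test_30uv_single_sample_step_removed(self, rng):
        trials = rng.standard_normal((50, 500))
        trials[5, 100:] += 30.0
        kept = reject_artifacts(trials)
        assert 5 not in kept

    def test_identical_clean_trials_all_kept(self):
        trials = np.tile(np.sin(np.linspace(0, 10, 500)), (20, 1))
        kept = reject_artifacts(trials)
        assert kept.tolist() == list(range(20))

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            reject_artifacts(rng.standard_normal((5, 100)))


class TestFeatureMatrices:
    def test_design_matrix_dimensions(self, features0):
        assert features0.X_pre.shape[1] == 400 + 40 + 120
        assert features0.X_evk.shape[1] == 400 + 40
        kinds = features0.pre_labels["kind"].value_counts()
        assert kinds["stP"] == 400 and kinds["stBHA"] == 40
        assert kinds["phase_sin"] == 60 and kinds["phase_cos"] == 60

    def test_kept_trials_sorted_subset(self, features0):
        kt = features0.kept_trials
        assert np.all(np.diff(kt) > 0)
        assert kt.min() >= 1 and kt.max() <= 480

    def test_windows_avoid_the_onset_guard_band(self, features0):
        pre_t = features0.pre_labels.loc[
            features0.pre_labels["kind"].isin(["stP", "stBHA"]), "tag"]
        evk_t = features0.evk_labels["tag"]
        assert pre_t.between(-500, -100, inclusive="left").all()
        assert evk_t.between(100, 500, inclusive="left").all()

    def test_phase_groups_are_adjacent_pairs(self, features0):
        g = features0.pre_groups
        assert np.all(g[:440] == -1)
        assert np.array_equal(g[440:], np.repeat(np.arange(60), 2))

    def test_extraction_is_deterministic(self, session, features0):
        again = build_feature_matrices(session, 0)
        assert np.array_equal(again.X_pre, features0.X_pre)
        assert np.array_equal(again.X_evk, features0.X_evk)

    def test_injected_artifact_trial_is_excluded(self, session):
        import copy
        s = copy.copy(session)
        traces = session.traces.copy()
        traces[0, 100, 900:] += 400.0   # huge step at trial 101
        s = type(session)(
            traces=traces, baseline_segments=session.baseline_segments,
            trial_table=session.trial_table,
            electrode_table=session.electrode_table,
            ground_truth=session.ground_truth, config=session.config)
        fs = build_feature_matrices(s, 0)
        assert 101 not in fs.kept_trials
        assert fs.X_pre.shape[0] == len(fs.kept_trials)
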