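"""Feature extraction: single-trial potential (stP), broadband high-frequency
activity (stBHA), pre-stimulus oscillatory phase, and artifact rejection.

The analysis windows are [-500, -100) ms (pre-stimulus, the proxy for the
endogenous state) and [100, 500) ms (post-stimulus) around stimulus onset;
the +/-100 ms guard band around onset is excluded so filter ringing cannot
leak stimulus-evoked activity into the pre-stimulus features or vice versa.

Per electrode and trial this yields
  * 400 stP samples per window (0.2-115 Hz band-passed voltage at 1000 Hz),
  * 40 stBHA samples per window (mean baseline-z-scored spectral power over
    40-100 Hz, at 100 Hz),
  * 60 pre-stimulus phases (DFT of the 400-point pre window, bins at
    2.5-150 Hz), encoded as (sin, cos) pairs for the group penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .simdata import SessionData

PRE_WINDOW_MS = (-500.0, -100.0)
POST_WINDOW_MS = (100.0, 500.0)


@dataclass
class FilterSpec:
    """Butterworth filter settings; filters are applied forward-backward
    (zero-phase) so they add no phase distortion."""

    line_stop_band: tuple[float, float] = (55.0, 65.0)
    line_order: int = 4
    stp_pass_band: tuple[float, float] = (0.2, 115.0)
    stp_order: int = 4

    def validate(self, fs: float) -> None:
        nyq = fs / 2
        for lo, hi in (self.line_stop_band, self.stp_pass_band):
            if not 0 < lo < hi < nyq:
                raise ValueError(f"band ({lo}, {hi}) outside (0, {nyq}) Hz")


@dataclass
class SpectralSpec:
    """Multitaper (Hann) PSD settings for stBHA.

    The PSD is evaluated on a 2 Hz frequency grid every 10 ms; each time step
    uses a Hann-tapered segment of ``analysis_window_ms`` centred on it,
    zero-padded to reach the 2 Hz grid.
    """

    psd_fmin: float = 2.0
    psd_fmax: float = 100.0
    psd_bin_hz: float = 2.0
    time_step_ms: float = 10.0
    analysis_window_ms: float = 200.0
    bha_band: tuple[float, float] = (40.0, 100.0)
    log_power: bool = False   # z-score raw power by default; log-power optional

    def validate(self) -> None:
        if not (self.psd_fmin <= self.bha_band[0] < self.bha_band[1] <= self.psd_fmax):
            raise ValueError("bha_band must lie within the PSD frequency range")


@dataclass
class ArtifactSpec:
    max_amp_sd: float = 5.0    # reject trials whose max |amp| > mean + k*SD
    max_jump_uv: float = 25.0  # reject trials with larger sample-to-sample steps


@dataclass
class FeatureSet:
    """Per-electrode design matrices over artifact-clean trials.

    ``X_pre`` has 400 stP + 40 stBHA + 120 phase-encoding columns (the 60
    phases as [sin t1, cos t1, ...]); ``X_evk`` has 400 stP + 40 stBHA.
    ``pre_groups`` assigns each phase (sin, cos) pair a group id (>= 0) and
    -1 to ungrouped columns, for the group elastic-net penalty.
    """

    electrode_id: str
    X_pre: np.ndarray
    X_evk: np.ndarray
    pre_labels: pd.DataFrame    # columns: kind, tag
    evk_labels: pd.DataFrame
    pre_groups: np.ndarray      # int, len == X_pre.shape[1]
    kept_trials: np.ndarray     # 1-based trial indices surviving rejection

    @property
    def n_trials(self) -> int:
        return self.X_pre.shape[0]


def remove_line_noise(trace: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-stop (55-65 Hz) for line noise."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    if trace.shape[-1] <= 3 * spec.line_order:
        raise ValueError("trace too short for the filter order")
    spec.validate(fs)
    sos = signal.butter(spec.line_order, spec.line_stop_band, btype="bandstop",
                        fs=fs, output="sos")
    return signal.sosfiltfilt(sos, trace, axis=-1)


def extract_stp(trace: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """stP: zero-phase 0.2-115 Hz band-pass of the (line-noise-free) trace."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    spec.validate(fs)
    sos = signal.butter(spec.stp_order, spec.stp_pass_band, btype="bandpass",
                        fs=fs, output="sos")
    return signal.sosfiltfilt(sos, trace, axis=-1)


def _psd_grid(spec: SpectralSpec, fs: float):
    nperseg = int(round(spec.analysis_window_ms * fs / 1000.0))
    nfft = int(round(fs / spec.psd_bin_hz))
    step = int(round(spec.time_step_ms * fs / 1000.0))
    return nperseg, nfft, step


def _spectrogram(x: np.ndarray, spec: SpectralSpec, fs: float):
    """Hann-tapered PSD every ``time_step_ms``; returns (freqs, centers_s, psd).

    ``x`` may be (..., time); psd is (..., freq, time_step) and ``centers_s``
    are segment-centre times in seconds from the start of ``x``.
    """
    nperseg, nfft, step = _psd_grid(spec, fs)
    freqs, t, psd = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg - step,
        nfft=nfft, mode="psd", detrend=False, axis=-1,
    )
    fmask = (freqs >= spec.psd_fmin - 1e-9) & (freqs <= spec.psd_fmax + 1e-9)
    psd = psd[..., fmask, :]
    if spec.log_power:
        psd = np.log(psd + 1e-20)
    return freqs[fmask], t, psd


@dataclass
class BaselineStats:
    """Per-frequency mean/variance of baseline PSD, used to z-score trials."""

    electrode_id: str
    freqs: np.ndarray
    mean: np.ndarray
    var: np.ndarray


def compute_baseline_stats(baseline_segments: np.ndarray, spec: SpectralSpec,
                           fs: float, electrode_id: str = "") -> BaselineStats:
    """Mean/variance of the PSD over all baseline time steps, per frequency bin."""
    spec.validate()
    segs = np.atleast_2d(np.asarray(baseline_segments, dtype=float))
    if segs.shape[-1] < fs:
        raise ValueError("baseline segments must be at least 1 s long")
    freqs, _, psd = _spectrogram(segs, spec, fs)   # (seg, freq, step)
    flat = psd.transpose(1, 0, 2).reshape(psd.shape[-2], -1)
    mean = flat.mean(axis=1)
    var = flat.var(axis=1)
    if np.any(var <= 0):
        raise ValueError("degenerate baseline: zero variance in a frequency bin")
    return BaselineStats(electrode_id=electrode_id, freqs=freqs, mean=mean, var=var)


def extract_stbha(trials: np.ndarray, baseline_stats: BaselineStats,
                  spec: SpectralSpec, fs: float, epoch_start_ms: float,
                  electrode_id: str = "") -> tuple[np.ndarray, np.ndarray]:
    """stBHA series: mean baseline-z-scored PSD over 40-100 Hz, every 10 ms.

    Returns ``(centers_ms, stbha)`` with ``stbha`` shaped (trial, step) and
    ``centers_ms`` the step centres relative to stimulus onset.
    """
    if electrode_id and baseline_stats.electrode_id and (
            electrode_id != baseline_stats.electrode_id):
        raise ValueError(
            f"baseline stats from electrode {baseline_stats.electrode_id!r} "
            f"applied to {electrode_id!r}"
        )
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    freqs, t, psd = _spectrogram(trials, spec, fs)  # (trial, freq, step)
    z = (psd - baseline_stats.mean[:, None]) / np.sqrt(baseline_stats.var)[:, None]
    band = (freqs >= spec.bha_band[0]) & (freqs <= spec.bha_band[1])
    stbha = z[:, band, :].mean(axis=1)
    centers_ms = epoch_start_ms + t * 1000.0
    return centers_ms, stbha


def extract_phase(trace_window: np.ndarray, fs: float = 1000.0,
                  n_phases: int = 60) -> np.ndarray:
    """Phases of the 400-point pre-stimulus window DFT at 2.5-150 Hz.

    The DC bin carries no phase, so the 60 features are the bins at
    2.5, 5, ..., 150 Hz.  Accepts (..., 400) arrays.
    """
    x = np.asarray(trace_window, dtype=float)
    expected = int(round(0.4 * fs))
    if x.shape[-1] != expected:
        raise ValueError(f"phase window must have {expected} samples, got {x.shape[-1]}")
    spec = np.fft.rfft(x, axis=-1)
    return np.angle(spec[..., 1:n_phases + 1])


def encode_phase(theta: np.ndarray) -> np.ndarray:
    """Map phases to interleaved [sin t1, cos t1, sin t2, cos t2, ...] columns."""
    theta = np.atleast_2d(theta)
    out = np.empty(theta.shape[:-1] + (2 * theta.shape[-1],))
    out[..., 0::2] = np.sin(theta)
    out[..., 1::2] = np.cos(theta)
    return out


def reject_artifacts(trials: np.ndarray,
                     spec: ArtifactSpec | None = None) -> np.ndarray:
    """Indices (0-based, increasing) of trials surviving artifact rejection.

    Rejects trials whose maximum |amplitude| exceeds the mean + k SD of the
    per-trial max-amplitude distribution, and trials with any
    consecutive-sample change above ``max_jump_uv``.
    """
    spec = spec or ArtifactSpec()
    trials = np.asarray(trials, dtype=float)
    if trials.shape[0] < 10:
        raise ValueError("artifact rejection requires at least 10 trials")
    max_amp = np.abs(trials).max(axis=1)
    amp_ok = max_amp <= max_amp.mean() + spec.max_amp_sd * max_amp.std()
    jump_ok = np.abs(np.diff(trials, axis=1)).max(axis=1) <= spec.max_jump_uv
    kept = np.flatnonzero(amp_ok & jump_ok)
    if kept.size == 0:
        raise ValueError("all trials rejected as artifacts")
    return kept


def _window_slice(epoch_start_ms: float, fs: float,
                  window_ms: tuple[float, float]) -> slice:
    i0 = int(round((window_ms[0] - epoch_start_ms) * fs / 1000.0))
    i1 = int(round((window_ms[1] - epoch_start_ms) * fs / 1000.0))
    return slice(i0, i1)


def build_feature_matrices(
    session: SessionData,
    electrode_index: int,
    filter_spec: FilterSpec | None = None,
    spectral_spec: SpectralSpec | None = None,
    artifact_spec: ArtifactSpec | None = None,
) -> FeatureSet:
    """Full preprocessing chain for one electrode: line-noise removal ->
    artifact rejection -> stP / stBHA / phase extraction -> X_pre, X_evk."""
    filter_spec = filter_spec or FilterSpec()
    spectral_spec = spectral_spec or SpectralSpec()
    fs = session.sampling_rate
    start_ms = session.epoch_window_ms[0]
    eid = str(session.electrode_table["electrode_id"].iloc[electrode_index])

    raw = session.traces[electrode_index]
    clean = remove_line_noise(raw, filter_spec, fs)
    kept0 = reject_artifacts(clean, artifact_spec)
    clean = clean[kept0]

    stp = extract_stp(clean, filter_spec, fs)
    baseline = remove_line_noise(
        session.baseline_segments[electrode_index], filter_spec, fs
    )
    bstats = compute_baseline_stats(baseline, spectral_spec, fs, electrode_id=eid)
    centers_ms, stbha = extract_stbha(
        clean, bstats, spectral_spec, fs, start_ms, electrode_id=eid
    )

    pre_sl = _window_slice(start_ms, fs, PRE_WINDOW_MS)
    post_sl = _window_slice(start_ms, fs, POST_WINDOW_MS)
    stp_pre = stp[:, pre_sl]
    stp_post = stp[:, post_sl]

    pre_steps = (centers_ms >= PRE_WINDOW_MS[0] - 1e-6) & (
        centers_ms < PRE_WINDOW_MS[1] - 1e-6)
    post_steps = (centers_ms >= POST_WINDOW_MS[0] - 1e-6) & (
        centers_ms < POST_WINDOW_MS[1] - 1e-6)
    stbha_pre = stbha[:, pre_steps]
    stbha_post = stbha[:, post_steps]

    theta = extract_phase(clean[:, pre_sl], fs=fs)
    phase_enc = encode_phase(theta)

    X_pre = np.hstack([stp_pre, stbha_pre, phase_enc])
    X_evk = np.hstack([stp_post, stbha_post])

    stp_t = np.arange(PRE_WINDOW_MS[0], PRE_WINDOW_MS[1], 1000.0 / fs)
    stp_t_post = np.arange(POST_WINDOW_MS[0], POST_WINDOW_MS[1], 1000.0 / fs)
    phase_freqs = 2.5 * np.arange(1, theta.shape[-1] + 1)
    pre_labels = pd.DataFrame(
        {
            "kind": (["stP"] * stp_pre.shape[1] + ["stBHA"] * stbha_pre.shape[1]
                     + [("phase_sin" if i % 2 == 0 else "phase_cos")
                        for i in range(phase_enc.shape[1])]),
            "tag": (list(stp_t) + list(centers_ms[pre_steps])
                    + [f for f in phase_freqs for _ in (0, 1)]),
        }
    )
    evk_labels = pd.DataFrame(
        {
            "kind": ["stP"] * stp_post.shape[1] + ["stBHA"] * stbha_post.shape[1],
            "tag": list(stp_t_post) + list(centers_ms[post_steps]),
        }
    )
    n_ungrouped = stp_pre.shape[1] + stbha_pre.shape[1]
    pre_groups = np.concatenate(
        [np.full(n_ungrouped, -1, dtype=int),
         np.repeat(np.arange(theta.shape[-1]), 2)]
    )

    return FeatureSet(
        electrode_id=eid,
        X_pre=X_pre,
        X_evk=X_evk,
        pre_labels=pre_labels,
        evk_labels=evk_labels,
        pre_groups=pre_groups,
        kept_trials=session.trial_table["trial_index"].to_numpy()[kept0],
    )


def save_features(fs: FeatureSet, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"features_{fs.electrode_id}.h5"
    with h5py.File(path, "w") as f:
        f.create_dataset("X_pre", data=fs.X_pre)
        f.create_dataset("X_evk", data=fs.X_evk)
        f.create_dataset("pre_groups", data=fs.pre_groups)
        f.create_dataset("kept_trials", data=fs.kept_trials)
        f.attrs["electrode_id"] = fs.electrode_id
        f.attrs["pre_kinds"] = [str(k) for k in fs.pre_labels["kind"]]
        f.attrs["evk_kinds"] = [str(k) for k in fs.evk_labels["kind"]]
        f.create_dataset("pre_tags", data=np.asarray(fs.pre_labels["tag"], dtype=float))
        f.create_dataset("evk_tags", data=np.asarray(fs.evk_labels["tag"], dtype=float))
    return path


def load_features(path: str | Path) -> FeatureSet:
    with h5py.File(path, "r") as f:
        pre_labels = pd.DataFrame(
            {"kind": list(f.attrs["pre_kinds"]), "tag": f["pre_tags"][...]}
        )
        evk_labels = pd.DataFrame(
            {"kind": list(f.attrs["evk_kinds"]), "tag": f["evk_tags"][...]}
        )
        return FeatureSet(
            electrode_id=str(f.attrs["electrode_id"]),
            X_pre=f["X_pre"][...],
            X_evk=f["X_evk"][...],
            pre_labels=pre_labels,
            evk_labels=evk_labels,
            pre_groups=f["pre_groups"][...].astype(int),
            kept_trials=f["kept_trials"][...].astype(int),
        )
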