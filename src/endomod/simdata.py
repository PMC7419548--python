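"""Synthetic iEEG session generator.

Emulates a 1-back visual category experiment: six balanced stimulus
categories (faces, bodies, words, tools, houses, scrambled), 30 images per
category shown twice, with exact-image repeats inserted after a fixed
fraction of base presentations.  Voltage traces are built from a 1/f
background, 10 and 15 Hz oscillations with per-trial random phase,
band-limited 40-100 Hz noise, and a post-stimulus category-specific evoked
template.  A latent "endogenous state" per electrode modulates the traces
through three mechanisms:

* a gain ``1 - gamma * g_t`` on the evoked category template: a high
  endogenous state suppresses the evoked response, weakening single-trial
  tuning in a way a boundary-shift model can partially compensate (gain
  modulation, the canonical interpretation of the modulation index),
* an additive drift ``kappa * g_t * u(t)`` along a fixed waveform ``u``
  independent of the presented stimulus: the negated template of the
  electrode's own network category, so a high state suppresses activity
  along the circuit's response pattern on every trial,
* a scaling ``(1 + c_g * g_t)`` of the pre-stimulus 40-100 Hz noise variance,
* a gain ``(1 + c_phi * cos(theta_15 - theta_0))`` on the evoked template set
  by the 15 Hz oscillatory phase at stimulus onset.

Electrode latents ``g`` load on a shared per-category network latent ``G``
(correlating electrodes of the same selectivity), ``G`` follows an AR(1)
process across trials, and reaction times on repeat trials of category ``c``
are ``mu_RT + b * G_c + noise`` -- so the state that modulates a circuit also
drives behaviour only for that circuit's category.

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` spawns (trial order, latents, RT noise, one
stream per electrode), so individual components are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

CATEGORY_NAMES = ("bodies", "faces", "words", "tools", "houses", "scrambled")

# Evoked-template design: damped sinusoids with category-specific latency and
# frequency, peaking inside the [100, 500] ms analysis window.  The default
# amplitude is calibrated so a linear 6-way classifier separates categories at
# a realistic d' of roughly 1-1.5 under the default noise floor.
_TEMPLATE_LATENCY_MS = (110.0, 150.0, 190.0, 230.0, 270.0, 310.0)
_TEMPLATE_FREQ_HZ = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
_TEMPLATE_TAU_MS = 130.0
# RMS over the [100, 500] ms analysis window; scaled by (5.5/f)^0.8 so that
# templates riding on the 1/f^2 background have comparable SNR across
# categories.
_TEMPLATE_RMS_UV = 3.5

# Each electrode responds with full amplitude to its network's category and
# attenuated amplitude to the others, making it category-selective.
_NONPREF_GAIN = 0.25

# Noise floor (microvolts).
_BG_SIGMA_UV = 12.0
_ALPHA_AMP_UV = 6.0
_OSC15_AMP_UV = 5.0
_HF_SIGMA_UV = 4.0


@dataclass
class ModulationParams:
    """Gains of the latent endogenous state on the observable signals.

    Setting ``additive_shift_gain``, ``prestim_power_gain``,
    ``phase_gate_depth`` and ``rt_slope`` all to zero yields a null session in
    which the latent state is statistically independent of the post-stimulus
    response and of behaviour.
    """

    additive_shift_gain: float = 3.0     # kappa, uV RMS of drift per unit g
    evoked_gain_mod: float = 0.3         # gamma: evoked gain (1 - gamma*g)
    prestim_power_gain: float = 1.0      # c_g >= 0, unitless
    phase_gate_depth: float = 0.6        # c_phi in [0, 1], unitless
    phase_gate_freq: float = 15.0        # Hz
    phase_gate_ref: float = 0.0          # theta_0, rad
    trial_ar_coefficient: float = 0.0    # rho of the AR(1) network latent
    network_loading: float = 0.8         # w, corr(g, G) loading
    rt_slope: float = 40.0               # ms per latent unit
    rt_intercept: float = 665.0          # ms
    rt_noise: float = 90.0               # ms (SD)

    def validate(self) -> None:
        if not abs(self.trial_ar_coefficient) < 1:
            raise ValueError("trial_ar_coefficient must satisfy |rho| < 1")
        if self.prestim_power_gain < 0:
            raise ValueError("prestim_power_gain must be >= 0")
        if not 0 <= self.phase_gate_depth <= 1:
            raise ValueError("phase_gate_depth must lie in [0, 1]")
        if not 0 <= self.evoked_gain_mod <= 1:
            raise ValueError("evoked_gain_mod must lie in [0, 1]")
        if not 0 <= self.network_loading <= 1:
            raise ValueError("network_loading must lie in [0, 1]")
        if self.rt_noise < 0:
            raise ValueError("rt_noise must be >= 0")

    def nulled(self) -> "ModulationParams":
        return dataclasses.replace(
            self,
            additive_shift_gain=0.0,
            evoked_gain_mod=0.0,
            prestim_power_gain=0.0,
            phase_gate_depth=0.0,
            rt_slope=0.0,
        )


@dataclass
class SessionConfig:
    """Design of one recording session.

    The default design is 6 categories x 30 images x 2 presentations = 360
    base presentations, with an exact repeat inserted after 1/3 of them,
    giving 480 trials (120 repeats).
    """

    n_categories: int = 6
    images_per_category: int = 30
    presentations_per_image: int = 2
    repeat_rule: float = 1.0 / 3.0
    sampling_rate: float = 1000.0
    epoch_window_ms: tuple[float, float] = (-900.0, 900.0)
    n_electrodes: int = 12
    electrodes_per_category_network: int = 2
    electrode_coordinates: np.ndarray | None = None   # (n_electrodes, 3) mm
    modulation_params: ModulationParams = field(default_factory=ModulationParams)
    n_baseline_segments: int = 4
    baseline_segment_s: float = 3.0
    rng_seed: int = 0

    @property
    def n_base_presentations(self) -> int:
        return self.images_per_category * self.n_categories * self.presentations_per_image

    @property
    def n_repeats(self) -> int:
        n_rep = self.repeat_rule * self.n_base_presentations
        if abs(n_rep - round(n_rep)) > 1e-9:
            raise ValueError(
                f"repeat_rule {self.repeat_rule} does not yield an integer repeat "
                f"count on {self.n_base_presentations} base presentations"
            )
        return int(round(n_rep))

    @property
    def n_trials(self) -> int:
        return self.n_base_presentations + self.n_repeats

    def validate(self) -> None:
        lo, hi = self.epoch_window_ms
        if lo > -500 or hi < 500:
            raise ValueError("epoch_window_ms must contain [-500, 500] ms")
        if self.n_electrodes % self.electrodes_per_category_network:
            raise ValueError(
                "n_electrodes must be a multiple of electrodes_per_category_network"
            )
        if self.n_electrodes // self.electrodes_per_category_network > self.n_categories:
            raise ValueError("more category networks than categories")
        self.n_repeats  # raises on a non-integer repeat count
        self.modulation_params.validate()


@dataclass
class GroundTruth:
    """Latent variables of a synthetic session, for recovery tests."""

    network_latent: np.ndarray   # (n_categories, n_trials) G_{c,t}
    electrode_latent: np.ndarray  # (n_electrodes, n_trials) g_{e,t}
    theta15: np.ndarray          # (n_electrodes, n_trials) 15 Hz phase at onset


@dataclass
class SessionData:
    traces: np.ndarray            # (n_electrodes, n_trials, n_samples) uV
    baseline_segments: np.ndarray  # (n_electrodes, n_segments, n_samples) uV
    trial_table: pd.DataFrame     # trial_index, image_id, category, is_repeat, rt_ms
    electrode_table: pd.DataFrame  # electrode_id, x_mm, y_mm, z_mm, network_category
    ground_truth: GroundTruth
    config: SessionConfig

    @property
    def sampling_rate(self) -> float:
        return self.config.sampling_rate

    @property
    def epoch_window_ms(self) -> tuple[float, float]:
        return self.config.epoch_window_ms


def category_templates(config: SessionConfig) -> np.ndarray:
    """Evoked waveforms s_c(t), one per category, over the epoch. (cat, time) uV."""
    fs = config.sampling_rate
    lo, hi = config.epoch_window_ms
    t_ms = np.arange(lo, hi, 1000.0 / fs)
    out = np.zeros((config.n_categories, t_ms.size))
    window = (t_ms >= 100.0) & (t_ms < 500.0)
    for c in range(config.n_categories):
        lat = _TEMPLATE_LATENCY_MS[c % 6]
        f = _TEMPLATE_FREQ_HZ[c % 6]
        rel = (t_ms - lat) / 1000.0
        active = rel >= 0
        out[c, active] = (
            np.exp(-rel[active] * 1000.0 / _TEMPLATE_TAU_MS)
            * np.sin(2 * np.pi * f * rel[active])
        )
        rms = np.sqrt(np.mean(out[c, window] ** 2))
        out[c] *= _TEMPLATE_RMS_UV * (5.5 / f) ** 0.8 / rms
    return out


def drift_waveform(config: SessionConfig,
                   network_category: int | None = None) -> np.ndarray:
    """Fixed drift waveform u(t) of an electrode's endogenous state.

    The drift is independent of the presented stimulus category: on *every*
    trial the electrode's evoked window receives ``kappa * g_t * u(t)``.  For
    an electrode in the network selective for category ``network_category``
    (1-based), u is the negated template of that category, normalized to unit
    RMS over the analysis window: a high endogenous state suppresses activity
    along the circuit's own response pattern.  Because the classifier must
    read exactly that pattern to discriminate the preferred category, this
    common-mode fluctuation cannot be evaded by feature selection, making it
    compensable from the pre-stimulus state (and giving the modulation index
    a consistent positive coupling to g in every category network).  With
    ``network_category=None`` the negated mean template is returned.
    """
    templates = category_templates(config)
    if network_category is None:
        u = -templates.mean(axis=0)
    else:
        u = -templates[network_category - 1]
    fs = config.sampling_rate
    lo, hi = config.epoch_window_ms
    t_ms = np.arange(lo, hi, 1000.0 / fs)
    window = (t_ms >= 100.0) & (t_ms < 500.0)
    return u / np.sqrt(np.mean(u[window] ** 2))


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, int],
                      fs: float, sigma: float) -> np.ndarray:
    """Rows of 1/f-amplitude noise with RMS ``sigma``."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = (freqs >= 0.5) & (freqs <= 200.0)
    amp[nz] = 1.0 / freqs[nz]
    spec = amp * (rng.standard_normal(shape[:-1] + (freqs.size,))
                  + 1j * rng.standard_normal(shape[:-1] + (freqs.size,)))
    x = np.fft.irfft(spec, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True) + 1e-30
    return sigma * x


def _band_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float,
                band: tuple[float, float], sigma: float) -> np.ndarray:
    """Rows of band-limited Gaussian noise with RMS ``sigma``."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros(shape[:-1] + (freqs.size,), dtype=complex)
    spec[..., mask] = (rng.standard_normal(shape[:-1] + (int(mask.sum()),))
                       + 1j * rng.standard_normal(shape[:-1] + (int(mask.sum()),)))
    x = np.fft.irfft(spec, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True) + 1e-30
    return sigma * x


def _make_trial_table(config: SessionConfig, rng: np.random.Generator,
                      rt_rng: np.random.Generator,
                      network_latent: np.ndarray | None = None) -> pd.DataFrame:
    """Randomized balanced base sequence with exact repeats inserted.

    Repeats immediately follow their base presentation, so every repeat trial
    repeats the image of the directly preceding trial.  RTs are filled later
    (they depend on the latent state) unless ``network_latent`` is given.
    """
    n_cat = config.n_categories
    n_img = config.images_per_category
    base_images = np.tile(
        np.arange(n_cat * n_img), config.presentations_per_image
    )
    rng.shuffle(base_images)
    repeat_after = np.zeros(base_images.size, dtype=bool)
    idx = rng.choice(base_images.size, size=config.n_repeats, replace=False)
    repeat_after[idx] = True

    image_id, is_repeat = [], []
    for img, rep in zip(base_images, repeat_after):
        image_id.append(img)
        is_repeat.append(False)
        if rep:
            image_id.append(img)
            is_repeat.append(True)
    image_id = np.asarray(image_id)
    is_repeat = np.asarray(is_repeat)
    category = image_id // n_img + 1  # 1-based labels

    table = pd.DataFrame(
        {
            "trial_index": np.arange(1, image_id.size + 1),
            "image_id": image_id,
            "category": category,
            "is_repeat": is_repeat,
        }
    )
    rt = np.full(image_id.size, np.nan)
    if network_latent is not None:
        mod = config.modulation_params
        rep_idx = np.flatnonzero(is_repeat)
        g_net = network_latent[category[rep_idx] - 1, rep_idx]
        rt[rep_idx] = (
            mod.rt_intercept
            + mod.rt_slope * g_net
            + mod.rt_noise * rt_rng.standard_normal(rep_idx.size)
        )
        rt[rep_idx] = np.maximum(rt[rep_idx], 150.0)
    table["rt_ms"] = rt
    return table


def _default_coordinates(config: SessionConfig) -> np.ndarray:
    """Networks 40 mm apart along x; electrodes within a network 25 mm apart."""
    per = config.electrodes_per_category_network
    coords = np.zeros((config.n_electrodes, 3))
    for e in range(config.n_electrodes):
        net, k = divmod(e, per)
        coords[e] = (40.0 * net, 25.0 * k, 0.0)
    return coords


def generate_session(config: SessionConfig) -> SessionData:
    """Generate one synthetic session; deterministic given ``config.rng_seed``."""
    config.validate()
    mod = config.modulation_params
    fs = config.sampling_rate
    lo, hi = config.epoch_window_ms
    n_samples = int(round((hi - lo) * fs / 1000.0))
    t_s = (lo + np.arange(n_samples) * 1000.0 / fs) / 1000.0  # seconds
    post_mask = t_s >= 0
    pre_mask = t_s < 0

    root = np.random.SeedSequence(config.rng_seed)
    ss_order, ss_latent, ss_rt, ss_elec = root.spawn(4)
    order_rng = np.random.default_rng(ss_order)
    latent_rng = np.random.default_rng(ss_latent)
    rt_rng = np.random.default_rng(ss_rt)
    elec_seeds = ss_elec.spawn(config.n_electrodes)

    # --- latent states -----------------------------------------------------
    n_trials = config.n_trials
    rho = mod.trial_ar_coefficient
    innov = latent_rng.standard_normal((config.n_categories, n_trials))
    G = np.empty_like(innov)
    G[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n_trials):
        G[:, t] = rho * G[:, t - 1] + scale * innov[:, t]

    per = config.electrodes_per_category_network
    net_of_elec = np.arange(config.n_electrodes) // per
    w = mod.network_loading
    eta = latent_rng.standard_normal((config.n_electrodes, n_trials))
    g = w * G[net_of_elec] + np.sqrt(1.0 - w**2) * eta

    # --- trial sequence and behaviour --------------------------------------
    trial_table = _make_trial_table(config, order_rng, rt_rng, network_latent=G)
    category = trial_table["category"].to_numpy()

    # --- traces -------------------------------------------------------------
    templates = category_templates(config)
    drift_by_network = np.stack(
        [drift_waveform(config, c + 1) for c in range(config.n_categories)]
    )
    traces = np.empty((config.n_electrodes, n_trials, n_samples))
    theta15 = np.empty((config.n_electrodes, n_trials))
    n_seg = config.n_baseline_segments
    seg_len = int(round(config.baseline_segment_s * fs))
    baseline = np.empty((config.n_electrodes, n_seg, seg_len))
    t_seg = np.arange(seg_len) / fs

    for e in range(config.n_electrodes):
        erng = np.random.default_rng(elec_seeds[e])
        x = _one_over_f_noise(erng, (n_trials, n_samples), fs, _BG_SIGMA_UV)
        phi10 = erng.uniform(-np.pi, np.pi, n_trials)
        phi15 = erng.uniform(-np.pi, np.pi, n_trials)
        theta15[e] = phi15
        x += _ALPHA_AMP_UV * np.cos(
            2 * np.pi * 10.0 * t_s[None, :] + phi10[:, None]
        )
        x += _OSC15_AMP_UV * np.cos(
            2 * np.pi * mod.phase_gate_freq * t_s[None, :] + phi15[:, None]
        )
        hf = _band_noise(erng, (n_trials, n_samples), fs, (40.0, 100.0), _HF_SIGMA_UV)
        power_scale = np.sqrt(np.maximum(1.0 + mod.prestim_power_gain * g[e], 0.05))
        hf[:, pre_mask] *= power_scale[:, None]
        x += hf
        # evoked gain: 15 Hz phase gate plus suppression by a high latent
        # state (high endogenous activity -> weaker, noisier evoked response)
        gate = np.maximum(
            1.0 + mod.phase_gate_depth * np.cos(phi15 - mod.phase_gate_ref)
            - mod.evoked_gain_mod * g[e], 0.05)
        cat_gain = np.where(category - 1 == net_of_elec[e], 1.0, _NONPREF_GAIN)
        evoked = templates[category - 1] * (gate * cat_gain)[:, None]
        u_e = drift_by_network[net_of_elec[e]]
        evoked = evoked + mod.additive_shift_gain * g[e][:, None] * u_e[None, :]
        x[:, post_mask] += evoked[:, post_mask]
        traces[e] = x

        b = _one_over_f_noise(erng, (n_seg, seg_len), fs, _BG_SIGMA_UV)
        bphi10 = erng.uniform(-np.pi, np.pi, n_seg)
        bphi15 = erng.uniform(-np.pi, np.pi, n_seg)
        b += _ALPHA_AMP_UV * np.cos(2 * np.pi * 10.0 * t_seg[None, :] + bphi10[:, None])
        b += _OSC15_AMP_UV * np.cos(
            2 * np.pi * mod.phase_gate_freq * t_seg[None, :] + bphi15[:, None]
        )
        b += _band_noise(erng, (n_seg, seg_len), fs, (40.0, 100.0), _HF_SIGMA_UV)
        baseline[e] = b

    coords = (
        np.asarray(config.electrode_coordinates, dtype=float)
        if config.electrode_coordinates is not None
        else _default_coordinates(config)
    )
    if coords.shape != (config.n_electrodes, 3):
        raise ValueError("electrode_coordinates must have shape (n_electrodes, 3)")
    electrode_table = pd.DataFrame(
        {
            "electrode_id": [f"e{e:03d}" for e in range(config.n_electrodes)],
            "x_mm": coords[:, 0],
            "y_mm": coords[:, 1],
            "z_mm": coords[:, 2],
            "network_category": net_of_elec + 1,
        }
    )

    return SessionData(
        traces=traces,
        baseline_segments=baseline,
        trial_table=trial_table,
        electrode_table=electrode_table,
        ground_truth=GroundTruth(network_latent=G, electrode_latent=g, theta15=theta15),
        config=config,
    )


def null_session(config: SessionConfig) -> SessionData:
    """A session with every modulation magnitude zeroed: the latent state is
    independent of the post-stimulus response and of RT by construction."""
    cfg = dataclasses.replace(
        config, modulation_params=config.modulation_params.nulled()
    )
    return generate_session(cfg)


# --- on-disk session directory ---------------------------------------------

def save_session(session: SessionData, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = session.config
    with h5py.File(directory / "traces.h5", "w") as f:
        f.create_dataset("traces", data=session.traces)
        f.create_dataset("baseline", data=session.baseline_segments)
        f.attrs["fs"] = cfg.sampling_rate
        f.attrs["window_ms"] = list(cfg.epoch_window_ms)
    session.trial_table.to_csv(directory / "trials.csv", index=False)
    session.electrode_table.to_csv(directory / "electrodes.csv", index=False)

    gt = session.ground_truth
    gt_cols = {"trial_index": np.arange(1, cfg.n_trials + 1)}
    for c in range(cfg.n_categories):
        gt_cols[f"G_cat{c + 1}"] = gt.network_latent[c]
    for e, eid in enumerate(session.electrode_table["electrode_id"]):
        gt_cols[f"g_{eid}"] = gt.electrode_latent[e]
        gt_cols[f"theta15_{eid}"] = gt.theta15[e]
    pd.DataFrame(gt_cols).to_csv(directory / "ground_truth.csv", index=False)

    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["epoch_window_ms"] = list(cfg.epoch_window_ms)
    if cfg.electrode_coordinates is not None:
        cfg_dict["electrode_coordinates"] = np.asarray(
            cfg.electrode_coordinates
        ).tolist()
    with open(directory / "config.json", "w") as f:
        json.dump(cfg_dict, f, indent=2)
    return directory


def load_session(directory: str | Path) -> SessionData:
    directory = Path(directory)
    with open(directory / "config.json") as f:
        cfg_dict = json.load(f)
    cfg_dict["epoch_window_ms"] = tuple(cfg_dict["epoch_window_ms"])
    if cfg_dict.get("electrode_coordinates") is not None:
        cfg_dict["electrode_coordinates"] = np.asarray(
            cfg_dict["electrode_coordinates"]
        )
    cfg_dict["modulation_params"] = ModulationParams(**cfg_dict["modulation_params"])
    config = SessionConfig(**cfg_dict)

    with h5py.File(directory / "traces.h5", "r") as f:
        traces = f["traces"][...]
        baseline = f["baseline"][...]
    trial_table = pd.read_csv(directory / "trials.csv")
    electrode_table = pd.read_csv(directory / "electrodes.csv")

    gt_df = pd.read_csv(directory / "ground_truth.csv")
    G = np.stack(
        [gt_df[f"G_cat{c + 1}"].to_numpy() for c in range(config.n_categories)]
    )
    eids = electrode_table["electrode_id"].tolist()
    g = np.stack([gt_df[f"g_{eid}"].to_numpy() for eid in eids])
    theta15 = np.stack([gt_df[f"theta15_{eid}"].to_numpy() for eid in eids])

    return SessionData(
        traces=traces,
        baseline_segments=baseline,
        trial_table=trial_table,
        electrode_table=electrode_table,
        ground_truth=GroundTruth(network_latent=G, electrode_latent=g, theta15=theta15),
        config=config,
    )
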