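"""Synthetic data generation for the cued Go/NoGo (VCPT) pipeline.

Everything downstream of acquisition is testable against this module:
trial sequences with the task's fixed timing, multi-channel EEG with
planted ERP components and artifacts (with ground truth returned for
recovery tests), behavioural response logs, and HTQ questionnaire
tables with controllable group structure and a planted ERP-change
covariate.

Timing of the task: each trial presents an S1-S2 stimulus pair with a
1100 ms onset asynchrony; successive trials start every 3000 ms.  A GO
trial is an animal cue followed by an animal; a NOGO trial is an animal
cue followed by a plant.  The default sequence has 400 trials, 200 GO
and 200 NOGO.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS_10_20, SAMPLING_RATE_HZ, channel_index, topography_from

# ---------------------------------------------------------------------------
# Task timing constants (ms)

SOA_MS = 1100            # S1 -> S2 onset asynchrony
TRIAL_SPACING_MS = 3000  # S1 -> next S1 onset spacing
STIMULUS_DURATION_MS = 100

_CONDITION_PAIRS = {
    "GO": ("animal", "animal"),
    "NOGO": ("animal", "plant"),
    "IGNORE": ("plant", "plant"),
    "NOVEL": ("plant", "human"),
}


def _substream(seed: int, *keys) -> np.random.Generator:
    """Named reproducible sub-stream of a single global seed."""
    tag = zlib.crc32("/".join(str(k) for k in keys).encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                                        spawn_key=(tag,)))


# ---------------------------------------------------------------------------
# Trial sequences

@dataclass(frozen=True)
class TrialSpec:
    """One S1-S2 trial of the VCPT."""
    index: int
    s1_category: str
    s2_category: str
    condition: str
    s1_onset_ms: float
    s2_onset_ms: float
    correct_response: str  # "press" or "withhold"


@dataclass
class TrialSequence:
    """Ordered VCPT trials."""
    trials: list[TrialSpec]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])

    @property
    def s2_onsets_ms(self) -> np.ndarray:
        return np.array([t.s2_onset_ms for t in self.trials])

    def condition_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.conditions, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def events(self) -> pd.DataFrame:
        """S2-locked event table (trial_index, condition, onsets)."""
        return pd.DataFrame({
            "trial_index": [t.index for t in self.trials],
            "condition": [t.condition for t in self.trials],
            "s1_onset_ms": [t.s1_onset_ms for t in self.trials],
            "s2_onset_ms": [t.s2_onset_ms for t in self.trials],
        })

    @property
    def duration_ms(self) -> float:
        return self.trials[-1].s1_onset_ms + TRIAL_SPACING_MS if self.trials else 0.0


def generate_trial_sequence(n_trials: int = 400, seed: int = 0, *,
                            include_ignore: bool = False,
                            include_novel: bool = False,
                            first_onset_ms: float = 1000.0) -> TrialSequence:
    """Pseudo-random VCPT sequence with equal counts per enabled condition.

    By default only GO and NOGO trials are generated (200 each at the
    default length); IGNORE and NOVEL trial types can be enabled but
    contribute no analysed ERPs downstream.
    """
    conditions = ["GO", "NOGO"]
    if include_ignore:
        conditions.append("IGNORE")
    if include_novel:
        conditions.append("NOVEL")
    k = len(conditions)
    if n_trials <= 0 or n_trials % k != 0:
        raise ValueError(
            f"n_trials={n_trials} must be a positive multiple of the number of "
            f"enabled condition types ({k}: {', '.join(conditions)}) so counts are equal"
        )
    labels = np.repeat(conditions, n_trials // k)
    rng = _substream(seed, "trials")
    rng.shuffle(labels)
    trials = []
    for i, cond in enumerate(labels):
        s1 = first_onset_ms + i * TRIAL_SPACING_MS
        s1cat, s2cat = _CONDITION_PAIRS[cond]
        trials.append(TrialSpec(
            index=i, s1_category=s1cat, s2_category=s2cat, condition=str(cond),
            s1_onset_ms=s1, s2_onset_ms=s1 + SOA_MS,
            correct_response="press" if cond == "GO" else "withhold",
        ))
    return TrialSequence(trials)


# ---------------------------------------------------------------------------
# ERP component and noise models

@dataclass
class ErpComponentModel:
    """A Gaussian-windowed ERP component planted in synthetic EEG.

    ``peak_latency_ms`` is relative to the locking stimulus onset
    (S2 by default); ``width_ms`` is the full width at half maximum of
    the Gaussian envelope; ``topography`` maps the component onto the
    19-channel montage.  ``conditions`` restricts the component to a
    subset of trial types.  ``amplitude_cv`` adds trial-to-trial
    lognormal-free gaussian amplitude variability (coefficient of
    variation).
    """
    name: str
    peak_latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: np.ndarray
    conditions: tuple[str, ...] = ("GO", "NOGO")
    lock: str = "s2"  # "s1" or "s2"
    amplitude_cv: float = 0.0

    def __post_init__(self):
        self.topography = np.asarray(self.topography, dtype=float)
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if self.topography.shape != (len(CHANNELS_10_20),):
            raise ValueError(
                f"topography must have exactly {len(CHANNELS_10_20)} entries "
                f"(one per channel of the 10-20 montage)")

    def waveform(self, time_ms: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian bump over ``time_ms`` (stimulus-locked)."""
        sigma = self.width_ms / 2.3548200450309493  # FWHM -> sd
        return np.exp(-0.5 * ((time_ms - self.peak_latency_ms) / sigma) ** 2)


def component(name: str, peak_latency_ms: float, width_ms: float,
              amplitude_uv: float, gains: dict[str, float], **kw) -> ErpComponentModel:
    """Convenience constructor taking a ``{channel: gain}`` topography."""
    return ErpComponentModel(name=name, peak_latency_ms=peak_latency_ms,
                             width_ms=width_ms, amplitude_uv=amplitude_uv,
                             topography=topography_from(gains), **kw)


# Canonical topographies: P3 GO parietal-max, P3 NOGO fronto-central,
# SPW broad centro-parietal; all positive-going at Fz/Cz.
_P3GO_TOPO = {"Pz": 1.0, "P3": 0.7, "P4": 0.7, "Cz": 0.7, "C3": 0.5, "C4": 0.5,
              "Fz": 0.4, "O1": 0.4, "O2": 0.4}
_P3NOGO_TOPO = {"Cz": 1.0, "Fz": 0.9, "F3": 0.6, "F4": 0.6, "C3": 0.6, "C4": 0.6,
                "Pz": 0.5, "Fp1": 0.3, "Fp2": 0.3}
_SPW_TOPO = {"Cz": 1.0, "Pz": 0.9, "Fz": 0.7, "C3": 0.6, "C4": 0.6,
             "P3": 0.6, "P4": 0.6}


def standard_components(p3go_uv: float = 6.0, p3nogo_uv: float = 9.0,
                        spw_go_uv: float = 2.0, spw_nogo_uv: float = 4.0,
                        amplitude_cv: float = 0.2) -> list[ErpComponentModel]:
    """Healthy-control component set for S2-locked GO/NOGO ERPs.

    The NOGO-specific excess of P3 (P3d) and of the slow positive wave
    (SPWd) are what the difference-wave analysis measures.
    """
    return [
        component("P3go", 330.0, 90.0, p3go_uv, _P3GO_TOPO,
                  conditions=("GO",), amplitude_cv=amplitude_cv),
        component("P3nogo", 400.0, 100.0, p3nogo_uv, _P3NOGO_TOPO,
                  conditions=("NOGO",), amplitude_cv=amplitude_cv),
        component("SPWgo", 650.0, 180.0, spw_go_uv, _SPW_TOPO,
                  conditions=("GO",), amplitude_cv=amplitude_cv),
        component("SPWnogo", 650.0, 180.0, spw_nogo_uv, _SPW_TOPO,
                  conditions=("NOGO",), amplitude_cv=amplitude_cv),
    ]


@dataclass
class NoiseModel:
    """Background EEG model: pink (1/f) process + posterior alpha + white noise.

    Amplitudes in microvolts; ``pink_sd_uv`` is the standard deviation of
    the pink process, ``alpha_amplitude_uv`` the peak amplitude of the
    10 Hz rhythm at its posterior maximum, ``white_sd_uv`` the white
    noise standard deviation.
    """
    pink_exponent: float = 1.0
    pink_sd_uv: float = 6.0
    alpha_amplitude_uv: float = 8.0
    white_sd_uv: float = 4.0

    @property
    def enabled(self) -> bool:
        return self.pink_sd_uv > 0 or self.alpha_amplitude_uv > 0 or self.white_sd_uv > 0


NOISE_OFF = NoiseModel(pink_sd_uv=0.0, alpha_amplitude_uv=0.0, white_sd_uv=0.0)

_ALPHA_TOPO = topography_from({"O1": 1.0, "O2": 1.0, "Pz": 0.8, "P3": 0.8, "P4": 0.8,
                               "T5": 0.6, "T6": 0.6, "Cz": 0.4, "C3": 0.3, "C4": 0.3,
                               "Fz": 0.2, "F3": 0.2, "F4": 0.2})

_BLINK_TOPO = topography_from({"Fp1": 1.0, "Fp2": 1.0, "F7": 0.4, "F8": 0.4,
                               "F3": 0.5, "F4": 0.5, "Fz": 0.4, "Cz": 0.15})

_MUSCLE_SITES = ("T3", "T4", "T5", "T6")


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, fs: float) -> np.ndarray:
    """FFT-shaped 1/f^exponent noise, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass
class SynthesisGroundTruth:
    """What was actually planted, for recovery tests."""
    events: pd.DataFrame                 # trial_index, condition, onsets
    component_amplitudes: pd.DataFrame   # trial_index x component amplitude (uV)
    artifacts: pd.DataFrame              # trial_index, artifact in {none, blink, muscle}
    components: list[ErpComponentModel]


def synthesize_eeg(sequence: TrialSequence,
                   components: list[ErpComponentModel],
                   noise: NoiseModel = NoiseModel(),
                   artifact_rate: float = 0.0,
                   seed: int = 0,
                   blink_amplitude_uv: float = 150.0,
                   muscle_amplitude_uv: float = 60.0,
                   pad_ms: float = 2000.0):
    """Continuous 19-channel EEG with planted components and artifacts.

    Returns ``(EEGRecording, SynthesisGroundTruth)``.  Artifacts (half-sine
    blinks maximal at Fp1/Fp2, 26-38 Hz muscle bursts maximal at temporal
    sites) are planted within the S2 epoch window of randomly selected
    trials so they trip the amplitude-band rejection rules independently
    of the planted ERPs.
    """
    from .preprocess import EEGRecording  # local import to avoid a cycle

    if not 0.0 <= artifact_rate <= 1.0:
        raise ValueError("artifact_rate must be in [0, 1]")
    fs = SAMPLING_RATE_HZ
    n_samples = int(np.ceil((sequence.duration_ms + pad_ms) * fs / 1000.0))
    n_ch = len(CHANNELS_10_20)
    data = np.zeros((n_ch, n_samples))
    t_ms = np.arange(n_samples) * 1000.0 / fs

    # --- background noise -------------------------------------------------
    if noise.enabled:
        rng_noise = _substream(seed, "noise")
        for ci in range(n_ch):
            if noise.pink_sd_uv > 0:
                data[ci] += noise.pink_sd_uv * _pink_noise(
                    rng_noise, n_samples, noise.pink_exponent, fs)
            if noise.white_sd_uv > 0:
                data[ci] += noise.white_sd_uv * rng_noise.standard_normal(n_samples)
        if noise.alpha_amplitude_uv > 0:
            # narrowband (8-12 Hz) noise rather than a pure sinusoid, so the
            # rhythm's phase drifts and is not locked to the fixed trial grid
            from scipy.signal import butter, sosfiltfilt
            sos = butter(4, [8.0 / (fs / 2), 12.0 / (fs / 2)], btype="bandpass",
                         output="sos")
            alpha = sosfiltfilt(sos, rng_noise.standard_normal(n_samples))
            alpha /= alpha.std()
            rms = noise.alpha_amplitude_uv / np.sqrt(2.0)
            data += rms * np.outer(_ALPHA_TOPO, alpha)

    # --- planted components ----------------------------------------------
    rng_amp = _substream(seed, "amplitudes")
    amp_records: dict[str, np.ndarray] = {}
    for comp in components:
        amps = np.zeros(sequence.n_trials)
        for trial in sequence.trials:
            if trial.condition not in comp.conditions:
                continue
            a = comp.amplitude_uv
            if comp.amplitude_cv > 0:
                a *= max(0.0, 1.0 + comp.amplitude_cv * rng_amp.standard_normal())
            amps[trial.index] = a
            onset = trial.s1_onset_ms if comp.lock == "s1" else trial.s2_onset_ms
            # support of the bump: +-3 sd
            sigma = comp.width_ms / 2.3548200450309493
            lo = int(max(0, np.floor((onset + comp.peak_latency_ms - 3.5 * sigma) * fs / 1000)))
            hi = int(min(n_samples, np.ceil((onset + comp.peak_latency_ms + 3.5 * sigma) * fs / 1000)))
            bump = a * comp.waveform(t_ms[lo:hi] - onset)
            data[:, lo:hi] += np.outer(comp.topography, bump)
        amp_records[comp.name] = amps

    # --- artifacts ---------------------------------------------------------
    rng_art = _substream(seed, "artifacts")
    kinds = np.full(sequence.n_trials, "none", dtype=object)
    for trial in sequence.trials:
        if rng_art.uniform() >= artifact_rate:
            continue
        kind = "blink" if rng_art.uniform() < 0.5 else "muscle"
        kinds[trial.index] = kind
        # place within the S2 epoch window [-200, +800) ms
        if kind == "blink":
            dur_ms = 400.0
            start_ms = trial.s2_onset_ms + rng_art.uniform(-200, 800 - dur_ms)
            lo = int(start_ms * fs / 1000)
            n = int(dur_ms * fs / 1000)
            shape = np.sin(np.pi * np.arange(n) / n)  # half-sine
            seg = blink_amplitude_uv * np.outer(_BLINK_TOPO, shape)
        else:
            dur_ms = 240.0
            start_ms = trial.s2_onset_ms + rng_art.uniform(-200, 800 - dur_ms)
            lo = int(start_ms * fs / 1000)
            n = int(dur_ms * fs / 1000)
            f = rng_art.uniform(26.0, 34.0)  # inside the 20-35 Hz detection band
            tt = np.arange(n) / fs
            burst = np.sin(2 * np.pi * f * tt + rng_art.uniform(0, 2 * np.pi))
            burst *= np.hanning(n)
            site = _MUSCLE_SITES[rng_art.integers(len(_MUSCLE_SITES))]
            topo = topography_from({site: 1.0})
            for neigh in _MUSCLE_SITES:
                if neigh != site:
                    topo[channel_index(neigh)] = 0.25
            seg = muscle_amplitude_uv * np.outer(topo, burst)
        hi = min(lo + seg.shape[1], n_samples)
        if lo < n_samples:
            data[:, lo:hi] += seg[:, :hi - lo]

    recording = EEGRecording(data=data, channel_names=list(CHANNELS_10_20),
                             sampling_rate_hz=fs)
    truth = SynthesisGroundTruth(
        events=sequence.events(),
        component_amplitudes=pd.DataFrame(
            {"trial_index": np.arange(sequence.n_trials), **amp_records}),
        artifacts=pd.DataFrame(
            {"trial_index": np.arange(sequence.n_trials), "artifact": kinds}),
        components=list(components),
    )
    return recording, truth


# ---------------------------------------------------------------------------
# Subject-level waveform simulation (for statistical calibration)

def smooth_noise(rng: np.random.Generator, shape: tuple, noise_sd_uv: float,
                 smooth_ms: float = 24.0, fs: float = SAMPLING_RATE_HZ) -> np.ndarray:
    """Temporally smooth gaussian noise with unit-calibrated per-sample SD.

    Used to emulate the residual noise of a per-subject trial average,
    which is band-limited rather than white.
    """
    x = rng.standard_normal(shape)
    sigma = smooth_ms * fs / 1000.0 / 2.3548200450309493
    if sigma > 0:
        from scipy.ndimage import gaussian_filter1d
        x = gaussian_filter1d(x, sigma, axis=-1, mode="wrap")
        x /= np.sqrt(1.0 / (2 * np.sqrt(np.pi) * sigma))  # restore unit SD
    return noise_sd_uv * x


def difference_effect(amplitude_uv: float = 3.0, peak_ms: float = 400.0,
                      width_ms: float = 120.0,
                      channel_gains: tuple[float, ...] = (0.6, 1.0),
                      time_ms: np.ndarray | None = None) -> np.ndarray:
    """Canonical NOGO-only (difference-wave) effect on a (channels, time) grid.

    Default grid is the S2 epoch axis (-200..796 ms at 4 ms) over the
    (Fz, Cz) pair with the effect maximal at Cz.
    """
    if time_ms is None:
        time_ms = np.arange(-200.0, 800.0, 4.0)
    sigma = width_ms / 2.3548200450309493
    bump = amplitude_uv * np.exp(-0.5 * ((time_ms - peak_ms) / sigma) ** 2)
    return np.outer(np.asarray(channel_gains, dtype=float), bump)


def simulate_subject_waveforms(n_subjects: int, effect: np.ndarray,
                               noise_sd_uv: float, seed: int,
                               smooth_ms: float = 24.0) -> np.ndarray:
    """Per-subject averaged waveforms = shared effect + smooth subject noise.

    ``effect`` is (channels, time); returns (n_subjects, channels, time).
    """
    rng = _substream(seed, "subject-waveforms")
    out = np.empty((n_subjects,) + effect.shape)
    for s in range(n_subjects):
        out[s] = effect + smooth_noise(rng, effect.shape, noise_sd_uv, smooth_ms)
    return out


# ---------------------------------------------------------------------------
# Behavioural logs

def generate_behavioural_log(sequence: TrialSequence,
                             omission_rate: float = 0.06,
                             commission_rate: float = 0.005,
                             rt_mean_ms: float = 420.0,
                             rt_sd_ms: float = 120.0,
                             seed: int = 0) -> pd.DataFrame:
    """Simulated button-press log for a VCPT run.

    GO trials are responded to with probability ``1 - omission_rate``;
    NOGO (and IGNORE/NOVEL) trials draw a press with probability
    ``commission_rate``.  Response times are normal, truncated to
    (0, 3000) ms relative to S2 onset.  Defaults approximate the error
    rates and response-time statistics of a chronic-PTSD cohort on this
    task (omission median ~12/200, RT ~420-430 ms).
    """
    for name, r in (("omission_rate", omission_rate), ("commission_rate", commission_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if rt_mean_ms <= 0 or rt_sd_ms < 0:
        raise ValueError("rt parameters must be positive")
    rng = _substream(seed, "behaviour")
    rows = []
    for trial in sequence.trials:
        rt = np.nan
        if trial.condition == "GO":
            if rng.uniform() >= omission_rate:
                rt = rng.normal(rt_mean_ms, rt_sd_ms)
                while not (0.0 < rt < 3000.0):
                    rt = rng.normal(rt_mean_ms, rt_sd_ms)
        else:
            if rng.uniform() < commission_rate:
                rt = rng.normal(rt_mean_ms, rt_sd_ms)
                while not (0.0 < rt < 3000.0):
                    rt = rng.normal(rt_mean_ms, rt_sd_ms)
        rows.append({"trial_index": trial.index, "condition": trial.condition,
                     "s1_onset_ms": trial.s1_onset_ms, "s2_onset_ms": trial.s2_onset_ms,
                     "response_time_ms": rt})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HTQ cohort

#: Per-item propensity to change under treatment (hyperarousal and the
#: activity-avoidance item change most, amnesia/avoidant-thought least),
#: loosely mirroring which symptoms move with this intervention.
_ITEM_CHANGE_WEIGHTS = np.array([
    1.0, 1.3, 0.6, 1.1, 0.6, 1.3, 0.9, 1.3, 1.3, 1.0, 1.5, 0.3, 0.8, 0.9, 0.3, 0.6,
])


@dataclass
class CohortConfig:
    """Generator knobs for a responder/non-responder/control cohort.

    ERP attenuations are fractions of the healthy-control component
    amplitude removed at baseline; ``p3d_post_recovery_responders`` is
    the fraction of the attenuation recovered post-treatment.  HTQ
    changes are mean total-score decreases (pre - post, positive =
    improvement) on the 1-4 scale.
    """
    n_controls: int = 107
    n_responders: int = 22
    n_non_responders: int = 25
    p3d_attenuation: float = 0.4
    spwd_attenuation_responders: float = 0.3
    spwd_attenuation_nonresponders: float = 0.6
    p3d_post_recovery_responders: float = 1.0
    htq_baseline_mean: float = 2.9
    htq_baseline_responder_shift: float = 0.3
    htq_change_responders: float = 1.2
    htq_change_nonresponders: float = 0.2
    htq_erp_latent_r: float = 0.45
    seed: int = 0

    def __post_init__(self):
        for name in ("n_controls", "n_responders", "n_non_responders"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p3d_attenuation", "spwd_attenuation_responders",
                     "spwd_attenuation_nonresponders", "p3d_post_recovery_responders"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 1.0 <= self.htq_baseline_mean <= 4.0:
            raise ValueError("htq_baseline_mean must be in [1, 4]")
        if not -1.0 <= self.htq_erp_latent_r <= 1.0:
            raise ValueError("htq_erp_latent_r must be in [-1, 1]")
        if self.htq_change_responders < 0.5:
            raise ValueError("htq_change_responders must be >= 0.5 "
                             "(the clinically significant decrease)")
        if self.htq_change_nonresponders > 0.4:
            raise ValueError("htq_change_nonresponders must be <= 0.4")


@dataclass
class HTQCohort:
    """Generated questionnaire tables plus planted ERP-change covariate."""
    htq: pd.DataFrame        # subject_id, timepoint, group, item_01..item_16
    metadata: pd.DataFrame   # subject_id, group, age, sex, medication
    erp_change: pd.DataFrame  # subject_id, cz_p3d_change_uv, pz_spwd_change_uv
    latent: pd.DataFrame     # subject_id, latent_z, total_decrease


def generate_htq_cohort(config: CohortConfig) -> HTQCohort:
    """HTQ pre/post tables for responders and non-responders.

    Item scores are integers in 1..4; totals live on the 1/16 grid.
    Responder subjects are constructed with a total-score decrease of at
    least 0.5 (so the clinical responder rule recovers the generated
    labels exactly); non-responders decrease by at most 0.4.  A latent
    factor couples the realised total decrease to a per-subject
    ERP-change covariate with correlation ``htq_erp_latent_r``.
    """
    cfg = config
    rng = _substream(cfg.seed, "htq")
    groups = (["responder"] * cfg.n_responders + ["non_responder"] * cfg.n_non_responders)
    n = len(groups)
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]

    # feasibility: a responder must be able to lose >= 8 sixteenths
    min_room = 16 * (cfg.htq_baseline_mean + cfg.htq_baseline_responder_shift - 1.0)
    if cfg.n_responders > 0 and min_room < 8:
        raise ValueError(
            f"infeasible score targets: baseline mean {cfg.htq_baseline_mean} leaves "
            f"less than the 8/16 decrease a responder requires")

    pre = np.zeros((n, 16), dtype=int)
    post = np.zeros((n, 16), dtype=int)
    decrease_16ths = np.zeros(n, dtype=int)
    z = rng.standard_normal(n)

    for s, grp in enumerate(groups):
        shift = cfg.htq_baseline_responder_shift if grp == "responder" else 0.0
        m = np.clip(cfg.htq_baseline_mean + shift + rng.normal(0, 0.25), 1.4, 3.9)
        items = np.clip(np.rint(m + rng.normal(0, 0.7, size=16)), 1, 4).astype(int)
        pre[s] = items
        room_down = int((items - 1).sum())
        room_up = int((4 - items).sum())
        if grp == "responder":
            target = 16 * cfg.htq_change_responders + 3.0 * z[s] + rng.normal(0, 1.5)
            k = int(np.clip(np.rint(target), 8, room_down))
            if room_down < 8:
                raise ValueError(f"infeasible score targets for subject {subject_ids[s]}")
        else:
            target = 16 * cfg.htq_change_nonresponders + 3.0 * z[s] + rng.normal(0, 1.5)
            k = int(np.clip(np.rint(target), -min(4, room_up), min(6, room_down)))
        decrease_16ths[s] = k
        items_post = items.copy()
        w = _ITEM_CHANGE_WEIGHTS.copy()
        step = -1 if k >= 0 else 1
        bound = 1 if k >= 0 else 4
        for _ in range(abs(k)):
            avail = items_post != bound
            if not avail.any():
                break
            p = w * avail
            j = rng.choice(16, p=p / p.sum())
            items_post[j] += step
        post[s] = items_post

    total_decrease = decrease_16ths / 16.0
    # ERP-change covariate correlated with the realised decrease
    r = cfg.htq_erp_latent_r
    d_std = ((total_decrease - total_decrease.mean()) / total_decrease.std()
             if n > 1 and total_decrease.std() > 0 else np.zeros(n))
    eps = rng.standard_normal(n)
    latent_erp = r * d_std + np.sqrt(max(0.0, 1 - r ** 2)) * eps
    resp_mask = np.array([g == "responder" for g in groups])
    base_uv = np.where(resp_mask, 2.0 * cfg.p3d_post_recovery_responders, 0.0)
    cz_change = base_uv + 1.2 * latent_erp
    pz_change = 0.5 * base_uv + 1.0 * (r * d_std + np.sqrt(max(0.0, 1 - r ** 2))
                                       * rng.standard_normal(n))

    med_p = np.where(resp_mask, 0.82, 0.52)
    metadata = pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "age": np.rint(rng.normal(np.where(resp_mask, 45.5, 50.0), 8.0)).astype(int),
        "sex": np.where(rng.uniform(size=n) < 0.5, "M", "F"),
        "medication": (rng.uniform(size=n) < med_p).astype(int),
    })
    item_cols = [f"item_{j + 1:02d}" for j in range(16)]
    rows = []
    for s in range(n):
        rows.append({"subject_id": subject_ids[s], "timepoint": "pre",
                     "group": groups[s], **dict(zip(item_cols, pre[s]))})
        rows.append({"subject_id": subject_ids[s], "timepoint": "post",
                     "group": groups[s], **dict(zip(item_cols, post[s]))})
    htq = pd.DataFrame(rows)
    erp_change = pd.DataFrame({"subject_id": subject_ids,
                               "cz_p3d_change_uv": cz_change,
                               "pz_spwd_change_uv": pz_change})
    latent = pd.DataFrame({"subject_id": subject_ids, "latent_z": z,
                           "total_decrease": total_decrease})
    return HTQCohort(htq=htq, metadata=metadata, erp_change=erp_change, latent=latent)


def cohort_components(group: str, phase: str, config: CohortConfig) -> list[ErpComponentModel]:
    """Component set for one group x phase cell of the cohort design.

    The NOGO-specific components (which carry P3d and SPWd) are
    attenuated in the PTSD groups at baseline; responders recover the
    P3d attenuation post-treatment while SPWd stays attenuated.
    """
    comps = standard_components()
    if group == "control":
        return comps
    if group == "responder":
        spw_att = config.spwd_attenuation_responders
        p3_att = config.p3d_attenuation
        if phase == "post":
            p3_att *= (1.0 - config.p3d_post_recovery_responders)
    elif group == "non_responder":
        spw_att = config.spwd_attenuation_nonresponders
        p3_att = config.p3d_attenuation
    else:
        raise ValueError(f"unknown group {group!r}")
    out = []
    for c in comps:
        if c.name == "P3nogo":
            out.append(replace(c, amplitude_uv=c.amplitude_uv * (1 - p3_att)))
        elif c.name == "SPWnogo":
            out.append(replace(c, amplitude_uv=c.amplitude_uv * (1 - spw_att)))
        else:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Cross-block (PLSC) simulation

def simulate_crossblock(n: int = 47, p: int = 16, q: int = 2,
                        latent_r: float = 0.8, seed: int = 0,
                        x_loadings: np.ndarray | None = None,
                        y_loadings: np.ndarray | None = None,
                        noise_sd: float = 0.6):
    """Rank-1 cross-block dataset for PLSC recovery tests.

    A latent score drives both blocks; the block-level latent scores
    correlate at ``latent_r``.  Returns ``(X, Y, x_loadings, y_loadings)``.
    """
    rng = _substream(seed, "crossblock")
    if x_loadings is None:
        x_loadings = np.zeros(p)
        x_loadings[: min(5, p)] = [1.0, 0.9, 0.8, 0.7, 0.6][: min(5, p)]
    if y_loadings is None:
        y_loadings = np.array([1.0, 0.4])[:q]
    zx = rng.standard_normal(n)
    zy = latent_r * zx + np.sqrt(max(0.0, 1 - latent_r ** 2)) * rng.standard_normal(n)
    X = np.outer(zx, x_loadings) + noise_sd * rng.standard_normal((n, p))
    Y = np.outer(zy, y_loadings) + noise_sd * rng.standard_normal((n, q))
    return X, Y, np.asarray(x_loadings, float), np.asarray(y_loadings, float)


# ---------------------------------------------------------------------------
# Plain-text I/O

def write_eeg_csv(recording, path: str | Path) -> None:
    """Channels x time matrix as CSV (header = channel names) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(recording.data.T, columns=recording.channel_names)
    df.to_csv(path, index=False, float_format="%.4f")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "sampling_rate_hz": recording.sampling_rate_hz,
        "units": "uV",
        "reference": recording.reference,
    }))


def read_eeg(path: str | Path):
    """Read an EEG recording from CSV (+ JSON sidecar) or EDF."""
    from .preprocess import EEGRecording

    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EEGRecording(data=raw.get_data() * 1e6,
                            channel_names=list(raw.ch_names),
                            sampling_rate_hz=float(raw.info["sfreq"]))
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return EEGRecording(data=df.to_numpy().T,
                        channel_names=list(df.columns),
                        sampling_rate_hz=float(meta.get("sampling_rate_hz", SAMPLING_RATE_HZ)),
                        reference=meta.get("reference", "linked ears"))
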