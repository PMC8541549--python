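"""Paired dry/gel EEG session simulator.

Generates, per subject, one continuous recording per task for each electrode
system:

* CHECK — checkerboard reversals every 0.45 s (300 reversals after a 10 s
  baseline) evoking an occipital pattern-reversal VEP (N75/P100),
* ASSR — 75 trials of 12 s amplitude-modulated tone (40 Hz modulation) with
  a 2–3 s jittered intertrial interval, a fronto-central AEP (N1/P1) in the
  first second of each trial and a 40 Hz steady-state component throughout,
* EOEC — 60 alternating eyes-open (5 s) / eyes-closed (3 s) segments with
  parieto-occipital alpha whose power is multiplied during eye closure.

Subject-level component amplitudes and latencies are latent variables shared
between the dry and gel sessions of a subject, so between-system correlation
is high by construction; the systems differ in noise (stronger low-frequency
drift and delta-band excess for dry) and in channel-corruption probability.
Background noise is 1/f (pink) + white sensor noise + 50 Hz line noise +
band-limited drift + stereotyped frontal blinks arriving as a Poisson
process. Every random draw descends from one master seed through independent
per-(subject, system, task) streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy import signal as sps

from .montage import Montage, make_montage
from .recording import EventList, Recording

logger = logging.getLogger(__name__)

_SYSTEM_CODE = {"dry": 0, "gel": 1}
_TASK_CODE = {"CHECK": 0, "ASSR": 1, "EOEC": 2}
_BAD_KINDS = ("flat", "high-amplitude", "drift")

#: component latencies (s) relative to stimulus onset; includes the
#: presentation-chain delay, matching the peak-search window defaults
COMPONENT_LATENCY = {"N75": 0.121, "P100": 0.153, "N1": 0.313, "P1": 0.410}
COMPONENT_WIDTH = {"N75": 0.015, "P100": 0.016, "N1": 0.024, "P1": 0.032}
COMPONENT_SIGN = {"N75": -1.0, "P100": 1.0, "N1": -1.0, "P1": 1.0}


@dataclass
class SimConfig:
    """Simulation parameters; defaults reproduce the study's conditions.

    Amplitudes are scalp-peak values in μV, noise levels are standard
    deviations in μV, ``alpha_ec_gain`` multiplies alpha-band *power* during
    eye closure, ``effect_scale_dry_delta`` multiplies the delta-band noise
    power of the dry system.
    """

    n_subjects: int = 15
    sample_rate: float = 1024.0
    montage_name: str = "10-10"

    # evoked components (scalp peak, μV)
    vep_amplitude_n75: float = 44.0
    vep_amplitude_p100: float = 48.0
    aep_amplitude_n1: float = 48.0
    aep_amplitude_p1: float = 52.0
    assr_amplitude: float = 0.6
    alpha_amplitude: float = 6.0
    alpha_ec_gain: float = 4.0

    # between-subject variability of latent amplitudes/latencies
    amplitude_cv: float = 0.25
    latency_jitter_sd: float = 0.004

    # noise (μV)
    pink_noise_sd: float = 8.0
    white_noise_sd: float = 2.0
    delta_noise_sd: float = 4.0
    # between-channel spread of the noise level (impedance heterogeneity;
    # dry multipin contacts vary more than gelled ones)
    channel_noise_cv_dry: float = 0.30
    channel_noise_cv_gel: float = 0.15
    drift_sd_dry: float = 20.0
    drift_sd_gel: float = 5.0
    line_noise_amp: float = 5.0
    blink_rate: float = 10.0  # events / min
    blink_amplitude: float = 120.0

    # channel corruption
    p_bad_channel_dry: float = 0.05
    p_bad_channel_gel: float = 0.02

    # dry/gel asymmetry of low-frequency power
    effect_scale_dry_delta: float = 2.0

    # task structure
    n_check_trials: int = 300
    check_interval: float = 0.45
    n_assr_trials: int = 75
    assr_trial_duration: float = 12.0
    assr_iti: tuple[float, float] = (2.0, 3.0)
    assr_modulation_freq: float = 40.0
    n_eoec_trials: int = 60
    eo_duration: float = 5.0
    ec_duration: float = 3.0
    baseline_duration: float = 10.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vep_amplitude_n75", "vep_amplitude_p100",
                     "aep_amplitude_n1", "aep_amplitude_p1", "assr_amplitude",
                     "alpha_amplitude", "pink_noise_sd", "white_noise_sd",
                     "delta_noise_sd", "drift_sd_dry", "drift_sd_gel",
                     "line_noise_amp", "blink_rate", "blink_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_bad_channel_dry", "p_bad_channel_gel"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.alpha_ec_gain < 0 or self.effect_scale_dry_delta < 0:
            raise ValueError("gain/scale parameters must be >= 0")
        highest = max(50.0, self.assr_modulation_freq)
        if self.sample_rate <= 2 * highest:
            raise ValueError(
                f"sample_rate must exceed twice the highest synthesized "
                f"frequency ({highest} Hz)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def reduced(self, **overrides) -> "SimConfig":
        """A down-scaled configuration for fast simulation experiments.

        Same generative model and effect structure, fewer trials and a lower
        sample rate; intended for calibration loops, not for emulating the
        full sessions.
        """
        kw = dict(sample_rate=256.0, n_check_trials=60, n_assr_trials=8,
                  assr_trial_duration=6.0, n_eoec_trials=12,
                  baseline_duration=2.0)
        kw.update(overrides)
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """What was injected into one subject/system session."""

    subject_id: int
    system: str
    amplitudes: dict  # component -> scalp-peak μV (subject latent)
    latencies: dict  # component -> s
    assr_amplitude: float
    alpha_ec_gain: float
    bad_channels: list  # (label, kind) with kind in {flat, high-amplitude, drift}
    blink_onsets: dict = field(default_factory=dict)  # task -> onset samples

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# noise primitives

def _pink_noise(rng, n_ch: int, n: int) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit variance per channel."""
    n_f = n // 2 + 1
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.zeros(n_f)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_ch, n_f))
            + 1j * rng.standard_normal((n_ch, n_f))) * shaping
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_noise(rng, n_ch: int, n: int, sr: float, low: float, high: float) -> np.ndarray:
    """Band-limited Gaussian noise, unit variance per channel."""
    x = rng.standard_normal((n_ch, n))
    sos = sps.butter(4, [low, high], btype="bandpass", fs=sr, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _drift(rng, n_ch: int, n: int, sr: float) -> np.ndarray:
    """Slow (<1 Hz) random-walk drift, unit variance per channel."""
    walk = np.cumsum(rng.standard_normal((n_ch, n)), axis=1)
    walk = sps.detrend(walk, axis=1)
    sos = sps.butter(4, 1.0, btype="lowpass", fs=sr, output="sos")
    walk = sps.sosfiltfilt(sos, walk, axis=1)
    sd = walk.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return walk / sd


def blink_template(sr: float, amplitude: float = 1.0) -> np.ndarray:
    """Stereotyped biphasic blink deflection, ~400 ms."""
    t = np.arange(int(round(0.4 * sr))) / sr
    w = (np.exp(-0.5 * ((t - 0.13) / 0.045) ** 2)
         - 0.35 * np.exp(-0.5 * ((t - 0.27) / 0.08) ** 2))
    return amplitude * w


def _gaussian_field(montage: Montage, center: np.ndarray, sigma: float) -> np.ndarray:
    d2 = np.sum((montage.positions - center) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


def component_field(montage: Montage, component: str) -> np.ndarray:
    """Fixed spatial pattern of an evoked component (peak value 1)."""
    pos = {l: p for l, p in zip(montage.labels, montage.positions)}

    def centre(*labels):
        return np.mean([pos[l] for l in labels if l in pos], axis=0)

    # widths reflect volume-conducted scalp fields: broad, with the named
    # region carrying the maximum
    if component in ("N75", "P100"):
        return _gaussian_field(montage, centre("Oz"), 0.65)
    if component in ("N1", "P1", "ASSR"):
        return _gaussian_field(montage, centre("Fz", "Cz"), 0.60)
    if component == "alpha":
        return _gaussian_field(montage, centre("Pz", "Oz"), 0.60)
    if component == "blink":
        return _gaussian_field(montage, np.array([0.0, 0.95]), 0.35)
    raise ValueError(f"unknown component {component!r}")


# ---------------------------------------------------------------------------
# subject-level latents

def _subject_latents(config: SimConfig, subject_id: int) -> tuple[dict, dict]:
    """Amplitude/latency latents shared by a subject's dry and gel sessions."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1000 + subject_id]))
    base = {"N75": config.vep_amplitude_n75, "P100": config.vep_amplitude_p100,
            "N1": config.aep_amplitude_n1, "P1": config.aep_amplitude_p1}
    sigma = np.sqrt(np.log1p(config.amplitude_cv ** 2))
    amplitudes = {}
    latencies = {}
    for comp, amp in base.items():
        amplitudes[comp] = float(amp * rng.lognormal(-sigma ** 2 / 2, sigma))
        latencies[comp] = float(COMPONENT_LATENCY[comp]
                                + rng.normal(0.0, config.latency_jitter_sd))
    amplitudes["ASSR"] = float(
        config.assr_amplitude * rng.lognormal(-sigma ** 2 / 2, sigma))
    amplitudes["alpha"] = float(
        config.alpha_amplitude * rng.lognormal(-sigma ** 2 / 2, sigma))
    return amplitudes, latencies


def _session_bad_channels(config: SimConfig, subject_id: int, system: str,
                          montage: Montage) -> list:
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 2000 + subject_id, _SYSTEM_CODE[system]]))
    p = config.p_bad_channel_dry if system == "dry" else config.p_bad_channel_gel
    bad = []
    for lab in montage.labels:
        if lab == "M2":  # reference electrode quality is managed separately
            continue
        if rng.random() < p:
            bad.append((lab, _BAD_KINDS[rng.integers(len(_BAD_KINDS))]))
    return bad


# ---------------------------------------------------------------------------
# task synthesis

def _task_events(config: SimConfig, task: str, rng) -> tuple[int, EventList]:
    """Sample count and event list of one task recording."""
    sr = config.sample_rate
    base = int(round(config.baseline_duration * sr))
    if task == "CHECK":
        step = int(round(config.check_interval * sr))
        onsets = base + step * np.arange(config.n_check_trials)
        n = int(onsets[-1] + step + sr)  # tail for the last epoch
        return n, EventList(onsets, ["reversal"] * config.n_check_trials)
    if task == "ASSR":
        dur = int(round(config.assr_trial_duration * sr))
        lo, hi = config.assr_iti
        itis = (rng.uniform(lo, hi, size=config.n_assr_trials) * sr).astype(int)
        onsets = base + np.concatenate([[0], np.cumsum(dur + itis[:-1])])
        n = int(onsets[-1] + dur + sr)
        return n, EventList(onsets, ["trial"] * config.n_assr_trials)
    if task == "EOEC":
        eo = int(round(config.eo_duration * sr))
        ec = int(round(config.ec_duration * sr))
        onsets, labels = [], []
        cursor = base
        for i in range(config.n_eoec_trials):
            if i % 2 == 0:
                onsets.append(cursor); labels.append("EO"); cursor += eo
            else:
                onsets.append(cursor); labels.append("EC"); cursor += ec
        n = int(cursor + sr)
        return n, EventList(np.array(onsets), labels)
    raise ValueError(f"unknown task {task!r}")


def _component_waveform(component: str, amplitude: float, latency: float,
                        sr: float, length_s: float) -> np.ndarray:
    t = np.arange(int(round(length_s * sr))) / sr
    w = COMPONENT_WIDTH[component]
    return (COMPONENT_SIGN[component] * amplitude
            * np.exp(-0.5 * ((t - latency) / w) ** 2))


def simulate_subject(config: SimConfig, subject_id: int, system: str,
                     tasks=("CHECK", "ASSR", "EOEC")
                     ) -> tuple[dict, GroundTruth]:
    """Simulate one subject/system session.

    Returns one continuous :class:`Recording` per task plus the injected
    ground truth. Reproducible: the same (seed, subject, system) yields
    bit-identical output.
    """
    if system not in _SYSTEM_CODE:
        raise ValueError(f"unknown system {system!r}")
    if not 0 <= subject_id < config.n_subjects:
        raise ValueError(f"subject_id {subject_id} outside 0..{config.n_subjects - 1}")
    sr = config.sample_rate
    montage = make_montage(system)
    n_ch = len(montage)
    amplitudes, latencies = _subject_latents(config, subject_id)
    bad_channels = _session_bad_channels(config, subject_id, system, montage)
    gt = GroundTruth(subject_id=subject_id, system=system,
                     amplitudes=amplitudes, latencies=latencies,
                     assr_amplitude=amplitudes["ASSR"],
                     alpha_ec_gain=config.alpha_ec_gain,
                     bad_channels=bad_channels)

    drift_sd = config.drift_sd_dry if system == "dry" else config.drift_sd_gel
    delta_sd = config.delta_noise_sd * (
        np.sqrt(config.effect_scale_dry_delta) if system == "dry" else 1.0)
    # per-channel noise gains: fixed per session, shared across its tasks
    noise_cv = (config.channel_noise_cv_dry if system == "dry"
                else config.channel_noise_cv_gel)
    gain_rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 3000 + subject_id, _SYSTEM_CODE[system]]))
    if noise_cv > 0:
        sigma_g = np.sqrt(np.log1p(noise_cv ** 2))
        channel_gain = gain_rng.lognormal(-sigma_g ** 2 / 2, sigma_g,
                                          size=n_ch)[:, None]
    else:
        channel_gain = np.ones((n_ch, 1))

    recordings = {}
    for task in tasks:
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, subject_id, _SYSTEM_CODE[system], _TASK_CODE[task]]))
        n, events = _task_events(config, task, rng)
        data = np.zeros((n_ch, n))

        # background noise (per-channel gains model impedance heterogeneity)
        if config.pink_noise_sd > 0:
            data += config.pink_noise_sd * channel_gain \
                * _pink_noise(rng, n_ch, n)
        if config.white_noise_sd > 0:
            data += config.white_noise_sd * channel_gain \
                * rng.standard_normal((n_ch, n))
        if delta_sd > 0:
            data += delta_sd * channel_gain * _band_noise(rng, n_ch, n, sr,
                                                          1.0, 4.0)
        if drift_sd > 0:
            data += drift_sd * _drift(rng, n_ch, n, sr)
        if config.line_noise_amp > 0:
            t = np.arange(n) / sr
            phases = rng.uniform(0, 2 * np.pi, size=n_ch)
            data += config.line_noise_amp * np.sin(
                2 * np.pi * 50.0 * t[None, :] + phases[:, None])

        # blinks (frontal, Poisson arrivals)
        blink_onsets = np.empty(0, dtype=int)
        if config.blink_rate > 0 and config.blink_amplitude > 0:
            tmpl = blink_template(sr, config.blink_amplitude)
            n_blinks = rng.poisson(config.blink_rate / 60.0 * n / sr)
            blink_onsets = np.sort(rng.integers(0, max(n - tmpl.size, 1),
                                                size=n_blinks))
            fld = component_field(montage, "blink")
            for onset in blink_onsets:
                stop = min(onset + tmpl.size, n)
                data[:, onset:stop] += np.outer(fld, tmpl[: stop - onset])
        gt.blink_onsets[task] = blink_onsets.tolist()

        # task-evoked content
        if task == "CHECK":
            for comp in ("N75", "P100"):
                wave = _component_waveform(comp, amplitudes[comp],
                                           latencies[comp], sr, 0.45)
                fld = component_field(montage, comp)
                for onset in events.onsets:
                    stop = min(onset + wave.size, n)
                    data[:, onset:stop] += np.outer(fld, wave[: stop - onset])
        elif task == "ASSR":
            for comp in ("N1", "P1"):
                wave = _component_waveform(comp, amplitudes[comp],
                                           latencies[comp], sr, 0.8)
                fld = component_field(montage, comp)
                for onset in events.onsets:
                    stop = min(onset + wave.size, n)
                    data[:, onset:stop] += np.outer(fld, wave[: stop - onset])
            fld = component_field(montage, "ASSR")
            dur = int(round(config.assr_trial_duration * sr))
            f_mod = config.assr_modulation_freq
            for onset in events.onsets:
                stop = min(onset + dur, n)
                t = np.arange(stop - onset) / sr
                data[:, onset:stop] += np.outer(
                    fld, amplitudes["ASSR"] * np.sin(2 * np.pi * f_mod * t))
        elif task == "EOEC":
            if amplitudes["alpha"] > 0:
                src = _band_noise(rng, 1, n, sr, 8.0, 12.0)[0]
                gain = np.ones(n)
                ec = int(round(config.ec_duration * sr))
                for onset, lab in zip(events.onsets, events.labels):
                    if lab == "EC":
                        gain[onset:onset + ec] = np.sqrt(config.alpha_ec_gain)
                fld = component_field(montage, "alpha")
                data += np.outer(fld, amplitudes["alpha"] * src * gain)

        # both systems are recorded against the right mastoid: the gel M2
        # data channel carries only a small residual, so re-referencing is
        # near-identity (as it is for the dry hardware reference)
        if "M2" in montage.labels:
            data[montage.index("M2")] = 0.3 * rng.standard_normal(n)

        # channel corruption (consistent across the session's tasks)
        for lab, kind in bad_channels:
            i = montage.index(lab)
            if kind == "flat":
                data[i] = 0.05 * rng.standard_normal(n)
            elif kind == "high-amplitude":
                data[i] += 120.0 * rng.standard_normal(n)
            elif kind == "drift":
                data[i] += 400.0 * _drift(rng, 1, n, sr)[0]

        recordings[task] = Recording(
            data=data, sample_rate=sr, channel_labels=list(montage.labels),
            events=events, system=system, subject_id=subject_id, task=task,
            reference_label="M2", montage=montage)
    return recordings, gt


@dataclass
class Cohort:
    """All simulated sessions of one paired-design cohort."""

    config: SimConfig
    sessions: dict  # (subject_id, system) -> {task: Recording}
    ground_truth: dict  # (subject_id, system) -> GroundTruth

    @property
    def n_subjects(self) -> int:
        return self.config.n_subjects

    def recordings(self, system: str, task: str) -> list:
        return [self.sessions[(s, system)][task]
                for s in range(self.n_subjects)
                if (s, system) in self.sessions]


def simulate_cohort(config: SimConfig, tasks=("CHECK", "ASSR", "EOEC"),
                    out_dir=None, format: str = "edf") -> Cohort:
    """Simulate paired dry/gel sessions for the whole cohort.

    When ``out_dir`` is given, every recording is written in the requested
    standard format together with events/montage sidecars and a JSON ground
    truth per session.
    """
    if config.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    sessions, truths = {}, {}
    for subject in range(config.n_subjects):
        for system in ("dry", "gel"):
            recs, gt = simulate_subject(config, subject, system, tasks=tasks)
            sessions[(subject, system)] = recs
            truths[(subject, system)] = gt
    cohort = Cohort(config=config, sessions=sessions, ground_truth=truths)
    if out_dir is not None:
        from . import io as eio
        import json
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (subject, system), recs in sessions.items():
            for rec in recs.values():
                eio.write_session(rec, out_dir, format=format)
            gt_path = out_dir / f"sub{subject:02d}_{system}_truth.json"
            gt_path.write_text(json.dumps(truths[(subject, system)].to_dict(),
                                          indent=1))
    return cohort
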