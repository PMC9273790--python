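"""Synthetic motor-imagery EEG with lateralized event-related desynchronization.

Each trial carries mu (10 Hz) and beta (20 Hz) rhythms on the three
sensorimotor channels C3, Cz and C4, embedded in power-law background
noise.  After the cue, the rhythm amplitude of the electrode contralateral
to the imagined hand (C3 for right-hand imagery, C4 for left-hand) is
attenuated by a factor

    1 - erd_depth * max(0, 1 - erd_decay * (t - cue_s)),

i.e. the desynchronization is strongest right after the cue and linearly
recovers at ``erd_decay`` per second, so windows taken late in the trial
carry a weaker class signal.  Ipsilateral and Cz rhythms are unmodulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError, ParameterError

__all__ = ["TrialParams", "EEGTrial", "generate_trial", "generate_dataset"]

#: channel order used throughout the package
CHANNELS = ("C3", "Cz", "C4")

LABELS = ("left", "right")


@dataclass(frozen=True)
class TrialParams:
    """Parameters of the synthetic trial generator.

    Attributes
    ----------
    fs : int
        Sampling rate in Hz; 128 (cue-paradigm recordings) or 250.
    trial_s : float
        Trial length in seconds.
    cue_s : float
        Cue onset in seconds; motor imagery starts here.
    erd_depth : float
        Fractional amplitude attenuation of the contralateral mu/beta
        rhythms during imagery, in [0, 1].  0 disables the class effect.
    erd_decay : float
        Linear recovery of the attenuation, per second.  With the default
        0.15/s an initial 80 % depth has shrunk to ~8 % six seconds after
        the cue, which reproduces the early-window > late-window accuracy
        trend the pipeline is meant to expose.
    noise_exponent : float
        Spectral slope alpha of the 1/f^alpha background noise (1 = pink).
    snr : float
        Rhythm power divided by noise power; ``math.inf`` disables noise.
    mu_hz, beta_hz : float
        Rhythm frequencies (mu 8-13 Hz band, beta 14-28 Hz band).
    mu_amp, beta_amp : float
        Baseline rhythm amplitudes in microvolts.
    seed : int
        RNG seed; the trial is a pure function of (params, label).
    """

    fs: int = 128
    trial_s: float = 9.0
    cue_s: float = 3.0
    erd_depth: float = 0.5
    erd_decay: float = 0.15
    noise_exponent: float = 1.0
    snr: float = 1.0
    mu_hz: float = 10.0
    beta_hz: float = 20.0
    mu_amp: float = 1.0
    beta_amp: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs not in (128, 250):
            raise ParameterError(f"fs must be 128 or 250, got {self.fs}")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ParameterError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if not self.cue_s < self.trial_s:
            raise ParameterError("cue_s must precede trial end")
        if self.snr <= 0:
            raise ParameterError("snr must be positive (use math.inf for no noise)")


@dataclass
class EEGTrial:
    """One labeled trial: channels x samples, channel order C3, Cz, C4."""

    data: np.ndarray
    fs: int
    label: str
    t0: float = 0.0
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise DataError(f"trial data must be (3, samples), got {self.data.shape}")
        if self.label not in LABELS:
            raise DataError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[CHANNELS.index(name)]


def _erd_envelope(t: np.ndarray, params: TrialParams) -> np.ndarray:
    """Amplitude gain applied to the contralateral rhythms over time."""
    gain = np.ones_like(t)
    mi = t >= params.cue_s
    depth = params.erd_depth * np.maximum(
        0.0, 1.0 - params.erd_decay * (t[mi] - params.cue_s)
    )
    gain[mi] = 1.0 - depth
    return gain


def _power_law_noise(rng: np.random.Generator, n: int, fs: int, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def generate_trial(params: TrialParams, label: str) -> EEGTrial:
    """Generate one labeled synthetic trial.

    The contralateral channel (C3 for ``right``, C4 for ``left``) has its
    mu+beta amplitude multiplied by the ERD envelope after the cue; the
    other channels are unmodulated.  Background noise is power-law with
    total power rhythm_power / snr per channel.
    """
    if label not in LABELS:
        raise ParameterError(f"label must be one of {LABELS}, got {label!r}")
    n = round(params.fs * params.trial_s)
    t = np.arange(n) / params.fs
    rng = np.random.default_rng(params.seed)

    contra = "C3" if label == "right" else "C4"
    envelope = _erd_envelope(t, params)

    data = np.empty((3, n))
    for ci, ch in enumerate(CHANNELS):
        phase_mu, phase_beta = rng.uniform(0.0, 2.0 * math.pi, size=2)
        rhythm = params.mu_amp * np.cos(2 * math.pi * params.mu_hz * t + phase_mu)
        rhythm += params.beta_amp * np.cos(2 * math.pi * params.beta_hz * t + phase_beta)
        if ch == contra:
            rhythm = rhythm * envelope
        data[ci] = rhythm

    if math.isfinite(params.snr):
        rhythm_power = 0.5 * (params.mu_amp**2 + params.beta_amp**2)
        noise_std = math.sqrt(rhythm_power / params.snr)
        for ci in range(3):
            data[ci] += noise_std * _power_law_noise(rng, n, params.fs, params.noise_exponent)

    return EEGTrial(data=data, fs=params.fs, label=label)


def generate_dataset(
    params: TrialParams, n_trials: int, seed: int | None = None
) -> list[EEGTrial]:
    """Generate a balanced, labeled dataset of ``n_trials`` trials.

    Labels alternate left/right so any prefix is near-balanced; per-trial
    seeds are derived deterministically from the master seed, so the whole
    dataset is reproducible bit-for-bit and different master seeds share
    the same label sequence.
    """
    if n_trials % 2 != 0:
        raise ParameterError(f"n_trials must be even for balanced labels, got {n_trials}")
    master = params.seed if seed is None else seed
    trials = []
    for i in range(n_trials):
        child = int(np.random.SeedSequence([master, i]).generate_state(1)[0] % 2**31)
        label = LABELS[i % 2]
        trial = generate_trial(replace(params, seed=child), label)
        trial.trial_id = i
        trials.append(trial)
    return trials
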