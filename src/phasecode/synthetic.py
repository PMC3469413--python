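"""Synthetic LFP + spike-train generator with controllable theta entrainment.

The generator emulates the statistical structure assumed by the decoding
analysis: a long continuous "stimulus" repeated over tens of trials, a slow
local-field-potential (LFP) oscillation whose phase trajectory is partially
locked to the stimulus across trials, and spikes from an inhomogeneous
Poisson process whose rate is modulated both by a stimulus-specific temporal
profile and by the oscillation phase.  An optional trial-unique background
rate component can be mixed in at a relative dB level to emulate acoustic
background noise.

Model
-----
One latent stimulus-locked phase trajectory ``phi*(t)`` is drawn per
recording (base frequency ``osc_freq_hz`` plus a slow random frequency
drift).  Each trial's oscillation uses ``phi*(t) + delta`` with a constant
per-trial offset ``delta ~ von Mises(0, entrainment_kappa)``; ``kappa = 0``
gives no stimulus locking, ``kappa = inf`` perfect locking.  The LFP is
``osc_amplitude * cos(phase) + noise_amplitude * (1/f noise)``.

The firing rate on trial ``j`` is::

    rate(t, j) = baseline * [1 + depth * s(t) + b_j(t)]
                          * [1 + coupling * cos(phase(t, j) - phi_pref)]

floored at zero, where ``s(t)`` is a smooth zero-mean unit-variance stimulus
profile shared across trials and ``b_j(t)`` is a trial-unique smooth
background profile whose r.m.s. relative to ``s(t)`` is set by
``noise_level_db`` (x dB -> amplitude factor ``10**(-x/20)``; +6 dB means
the target is 6 dB louder than the background).  Spikes are drawn by
thinning at 1 ms resolution (at most one spike per millisecond).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .rng import streams

__all__ = [
    "GeneratorConfig",
    "Recording",
    "generate_lfp",
    "generate_spikes",
    "generate_dataset",
    "save_recording",
    "load_recording",
]

#: Allowed relative background levels (dB of target r.m.s. re background).
NOISE_LEVELS_DB = (None, 6.0, 0.0, -6.0)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic recording generator.

    Durations are in ms, rates in Hz; the sampling rate is fixed at 1 kHz so
    one sample corresponds to one millisecond.
    """

    duration_ms: int = 52_000
    n_trials: int = 50
    sampling_rate_hz: int = 1000
    osc_freq_hz: float = 4.0
    entrainment_kappa: float = 8.0
    osc_amplitude: float = 1.0
    noise_amplitude: float = 1.5
    freq_jitter_hz: float = 0.2
    baseline_rate_hz: float = 10.0
    rate_mod_depth: float = 0.8
    phase_coupling: float = 0.6
    preferred_phase: float = 0.0
    profile_timescale_ms: float = 50.0
    noise_level_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.sampling_rate_hz != 1000:
            raise ValueError("sampling_rate_hz is fixed at 1000 (1 ms resolution)")
        if self.osc_freq_hz <= 0:
            raise ValueError("osc_freq_hz must be positive")
        if self.entrainment_kappa < 0:
            raise ValueError("entrainment_kappa must be non-negative")
        if self.osc_amplitude < 0 or self.noise_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.freq_jitter_hz < 0:
            raise ValueError("freq_jitter_hz must be non-negative")
        if self.baseline_rate_hz <= 0:
            raise ValueError("baseline_rate_hz must be positive")
        if not 0.0 <= self.rate_mod_depth <= 1.0:
            raise ValueError("rate_mod_depth must lie in [0, 1]")
        if not 0.0 <= self.phase_coupling <= 1.0:
            raise ValueError("phase_coupling must lie in [0, 1]")
        if self.profile_timescale_ms <= 0:
            raise ValueError("profile_timescale_ms must be positive")
        if self.noise_level_db is not None and not math.isfinite(self.noise_level_db):
            raise ValueError("noise_level_db must be finite or None")


@dataclass
class Recording:
    """One synthetic (or imported) unit: per-trial LFP rows and spike times.

    ``ground_truth`` retains the latent quantities the generator used
    (per-trial phase trajectory, stimulus rate profile, background
    profiles) so that tests can compare extracted against latent signals.
    Imported data carries an empty ground truth.
    """

    lfp: np.ndarray  # (n_trials, duration_ms)
    spikes: list[np.ndarray]  # per trial, sorted spike times in ms
    config: GeneratorConfig
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp, dtype=float)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be a (n_trials, duration_ms) matrix")
        n, L = self.lfp.shape
        if n != self.config.n_trials or L != self.config.duration_ms:
            raise ValueError("lfp shape does not match config")
        if len(self.spikes) != n:
            raise ValueError("one spike-time list per trial required")
        self.spikes = [np.sort(np.asarray(s, dtype=float)) for s in self.spikes]
        for s in self.spikes:
            if s.size and (s[0] < 0 or s[-1] >= L):
                raise ValueError("spike times must lie in [0, duration_ms)")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def duration_ms(self) -> int:
        return self.lfp.shape[1]


def _one_over_f_noise(rng: np.random.Generator, n_trials: int, n_samples: int) -> np.ndarray:
    """Rows of 1/f-power-shaped Gaussian noise, unit variance each."""
    n_freq = n_samples // 2 + 1
    spec = rng.standard_normal((n_trials, n_freq)) + 1j * rng.standard_normal((n_trials, n_freq))
    freqs = np.fft.rfftfreq(n_samples, d=1e-3)
    scale = np.zeros(n_freq)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])  # power ~ 1/f
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _smooth_profile(rng: np.random.Generator, n_samples: int, timescale_ms: float) -> np.ndarray:
    """Zero-mean unit-variance moving-average of white noise.

    The box width equals the requested correlation length, giving a smooth
    'naturalistic-like' slow profile without committing to any particular
    stimulus model.
    """
    size = max(int(round(timescale_ms)), 1)
    white = rng.standard_normal(n_samples)
    prof = uniform_filter1d(white, size=size, mode="wrap")
    prof = prof - prof.mean()
    sd = prof.std()
    if sd == 0:
        return np.zeros(n_samples)
    return prof / sd


def generate_lfp(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the LFP matrix and the latent per-trial phase trajectories.

    Returns ``(lfp, phase)`` with shapes ``(n_trials, duration_ms)``; the
    phase is wrapped to ``[0, 2*pi)``.
    """
    L, n = config.duration_ms, config.n_trials
    # Slow stimulus-locked drift of the instantaneous frequency.
    if config.freq_jitter_hz > 0:
        drift = config.freq_jitter_hz * _smooth_profile(rng, L, timescale_ms=500.0)
    else:
        drift = np.zeros(L)
    inst_freq = np.maximum(config.osc_freq_hz + drift, 0.0)
    phi_star = 2.0 * np.pi * np.cumsum(inst_freq) * 1e-3
    phi_star -= phi_star[0]  # phase zero (cosine peak) at t = 0

    kappa = config.entrainment_kappa
    if np.isinf(kappa):
        offsets = np.zeros(n)
    else:
        offsets = rng.vonmises(0.0, kappa, size=n)
    phase = phi_star[None, :] + offsets[:, None]

    lfp = config.osc_amplitude * np.cos(phase)
    if config.noise_amplitude > 0:
        lfp = lfp + config.noise_amplitude * _one_over_f_noise(rng, n, L)
    return lfp, np.mod(phase, 2.0 * np.pi)


def generate_spikes(
    config: GeneratorConfig,
    latent_phase: np.ndarray,
    rng_spikes: np.random.Generator,
    rng_profile: np.random.Generator,
    rng_noise: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], dict]:
    """Draw per-trial spike-time lists from the rate model.

    ``latent_phase`` is the ``(n_trials, duration_ms)`` phase matrix from
    :func:`generate_lfp`.  Returns ``(spike_lists, latents)`` where
    ``latents`` holds the stimulus profile and (if enabled) the per-trial
    background profiles.
    """
    L, n = config.duration_ms, config.n_trials
    latent_phase = np.asarray(latent_phase, dtype=float)
    if latent_phase.shape != (n, L):
        raise ValueError("latent_phase shape does not match config")

    profile = _smooth_profile(rng_profile, L, config.profile_timescale_ms)
    stim_term = 1.0 + config.rate_mod_depth * profile

    background = None
    if config.noise_level_db is not None:
        if rng_noise is None:
            raise ValueError("rng_noise required when noise_level_db is set")
        # x dB (target re background) -> background amplitude 10**(-x/20)
        # relative to the unit-r.m.s. stimulus profile.
        amp = 10.0 ** (-config.noise_level_db / 20.0)
        background = np.empty((n, L))
        for j in range(n):
            background[j] = amp * _smooth_profile(rng_noise, L, config.profile_timescale_ms)

    phase_term = 1.0 + config.phase_coupling * np.cos(latent_phase - config.preferred_phase)

    spikes: list[np.ndarray] = []
    for j in range(n):
        drive = stim_term if background is None else stim_term + background[j]
        rate = np.maximum(config.baseline_rate_hz * drive * phase_term[j], 0.0)
        p = np.clip(rate * 1e-3, 0.0, 1.0)  # per-ms thinning probability
        fired = rng_spikes.random(L) < p
        spikes.append(np.flatnonzero(fired).astype(float))

    latents = {"rate_profile": profile}
    if background is not None:
        latents["noise_profiles"] = background
    return spikes, latents


def generate_dataset(config: GeneratorConfig) -> Recording:
    """Compose LFP and spike generation from ``config.seed``.

    The named sub-streams (``lfp``, ``profile``, ``spikes``, ``noise``) are
    spawned independently from the master seed, so e.g. changing
    ``noise_level_db`` leaves the stimulus profile and the LFP untouched.
    Identical configs produce bit-identical recordings.
    """
    rngs = streams(config.seed)
    lfp, phase = generate_lfp(config, rngs["lfp"])
    spikes, latents = generate_spikes(
        config, phase, rngs["spikes"], rngs["profile"], rngs["noise"]
    )
    ground_truth = {"phase": phase, **latents}
    return Recording(lfp=lfp, spikes=spikes, config=config, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# Plain-text round-trip I/O
# ---------------------------------------------------------------------------

def save_recording(recording: Recording, directory: str | Path) -> None:
    """Write ``spikes.csv``, ``lfp.csv`` and ``config.json`` to a directory.

    Ground-truth latents are not persisted; they exist for testing only.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        (j, t) for j, times in enumerate(recording.spikes) for t in times
    ]
    pd.DataFrame(rows, columns=["trial", "spike_time_ms"]).to_csv(
        directory / "spikes.csv", index=False
    )
    np.savetxt(directory / "lfp.csv", recording.lfp, delimiter=",", fmt="%.17e")
    cfg = dataclasses.asdict(recording.config)
    (directory / "config.json").write_text(json.dumps(cfg, indent=2))


def load_recording(directory: str | Path) -> Recording:
    """Inverse of :func:`save_recording` (ground truth is not restored)."""
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    config = GeneratorConfig(**cfg)
    lfp = np.loadtxt(directory / "lfp.csv", delimiter=",", ndmin=2)
    table = pd.read_csv(directory / "spikes.csv")
    spikes = [np.empty(0) for _ in range(config.n_trials)]
    for trial, group in table.groupby("trial"):
        spikes[int(trial)] = group["spike_time_ms"].to_numpy(dtype=float)
    return Recording(lfp=lfp, spikes=spikes, config=config)
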