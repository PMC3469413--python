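"""Band-pass filtering, instantaneous phase, and inter-trial phase coherence.

Three filter families are supported for extracting a narrow band from the
broadband LFP: a Butterworth IIR band-pass (default: 3rd order, 2-6 Hz), a
Kaiser-window FIR band-pass, and a complex Morlet wavelet.  IIR/FIR filters
are applied forward-backward (zero phase) so that the extracted phase is not
lag-distorted relative to the spikes; the Morlet path convolves with a
complex kernel whose angle is used directly as the phase.

Phase convention: the phase is the angle of the analytic signal mapped to
``[0, 2*pi)``, with ``cos(2*pi*f*t)`` having phase 0 at its peaks.  All
phase-bin edges elsewhere in the package derive from this one convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "PhaseSeries",
    "bandpass",
    "instantaneous_phase",
    "extract_phase",
    "intertrial_phase_coherence",
    "window_coherence",
]

FS_HZ = 1000.0
NYQUIST_HZ = FS_HZ / 2.0
TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one narrow-band filter.

    ``low_hz``/``high_hz`` are the band edges for the Butterworth and Kaiser
    families.  The Morlet family instead uses ``center_hz`` and the spectral
    standard deviation ``sigma_hz`` (a common choice is 0.6/4 Hz at a 4 Hz
    center).
    """

    family: str = "butterworth"
    low_hz: float = 2.0
    high_hz: float = 6.0
    order: int = 3
    transition_hz: float = 1.0
    ripple_db: float = 0.01
    attenuation_db: float = 60.0
    center_hz: float | None = None
    sigma_hz: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("butterworth", "kaiser_fir", "morlet"):
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.family == "morlet":
            if self.center_hz is None or self.sigma_hz is None:
                raise ValueError("morlet requires center_hz and sigma_hz")
            if not 0 < self.center_hz < NYQUIST_HZ or self.sigma_hz <= 0:
                raise ValueError("invalid morlet parameters")
        else:
            if not 0 < self.low_hz < self.high_hz < NYQUIST_HZ:
                raise ValueError("band edges must satisfy 0 < low < high < Nyquist")

    @property
    def edge_margin_ms(self) -> float:
        """Samples closer than this to either end are edge-contaminated.

        Two time constants of the slowest band edge for IIR/FIR filters;
        three temporal standard deviations of the kernel for Morlet.
        """
        if self.family == "morlet":
            sigma_t_ms = 1000.0 / (TWO_PI * float(self.sigma_hz))
            return 3.0 * sigma_t_ms
        if self.family == "kaiser_fir":
            numtaps, _ = sps.kaiserord(self.attenuation_db, self.transition_hz / NYQUIST_HZ)
            return max((numtaps | 1) / 2.0, 2.0 * 1000.0 / self.low_hz)
        return 2.0 * 1000.0 / self.low_hz

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, data: dict) -> "FilterSpec":
        return cls(**data)


@dataclass
class PhaseSeries:
    """Instantaneous phase (and envelope) of one band, per trial and sample.

    Phase values lie in ``[0, 2*pi)``.
    """

    phase: np.ndarray  # (n_trials, n_samples)
    amplitude: np.ndarray | None = None
    band: FilterSpec | None = None

    def __post_init__(self) -> None:
        self.phase = np.atleast_2d(np.asarray(self.phase, dtype=float))
        if np.any(self.phase < 0) or np.any(self.phase >= TWO_PI):
            raise ValueError("phase values must lie in [0, 2*pi)")
        if self.amplitude is not None:
            self.amplitude = np.atleast_2d(np.asarray(self.amplitude, dtype=float))

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phase.shape[1]

    @property
    def edge_margin_ms(self) -> float:
        return self.band.edge_margin_ms if self.band is not None else 0.0


def _morlet_kernel(spec: FilterSpec) -> np.ndarray:
    sigma_t = 1.0 / (TWO_PI * spec.sigma_hz)  # seconds
    half = int(np.ceil(3.5 * sigma_t * FS_HZ))
    t = np.arange(-half, half + 1) / FS_HZ
    kernel = np.exp(2j * np.pi * spec.center_hz * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return kernel / np.abs(kernel).sum()


def bandpass(lfp: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply the band filter along the last axis.

    Returns a real matrix for the Butterworth/Kaiser families (zero-phase,
    forward-backward application) and a complex matrix for the Morlet family
    (the analytic band signal itself).  A warning is emitted when the data
    are too short for the filter's edge effects to decay.
    """
    x = np.asarray(lfp, dtype=float)
    n_samples = x.shape[-1]
    if n_samples < 2 * spec.edge_margin_ms:
        warnings.warn(
            "signal shorter than twice the filter edge margin; "
            "phase estimates may be edge-contaminated",
            stacklevel=2,
        )
    if spec.family == "butterworth":
        sos = sps.butter(
            spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=FS_HZ, output="sos"
        )
        return sps.sosfiltfilt(sos, x, axis=-1)
    if spec.family == "kaiser_fir":
        numtaps, beta = sps.kaiserord(spec.attenuation_db, spec.transition_hz / NYQUIST_HZ)
        numtaps |= 1  # odd length keeps the band-pass well defined
        taps = sps.firwin(
            numtaps,
            [spec.low_hz, spec.high_hz],
            window=("kaiser", beta),
            pass_zero=False,
            fs=FS_HZ,
        )
        return sps.filtfilt(taps, [1.0], x, axis=-1)
    kernel = _morlet_kernel(spec)
    flat = np.atleast_2d(x)
    out = np.empty(flat.shape, dtype=complex)
    for i, row in enumerate(flat):
        out[i] = sps.fftconvolve(row, kernel, mode="same")
    return out.reshape(x.shape) if x.ndim > 1 else out[0]


def instantaneous_phase(filtered: np.ndarray, band: FilterSpec | None = None) -> PhaseSeries:
    """Phase of the analytic signal, wrapped to ``[0, 2*pi)``.

    Real input is passed through the Hilbert transform; complex input (from
    the Morlet path) is used as the analytic signal directly.  NaNs raise.
    """
    x = np.atleast_2d(np.asarray(filtered))
    if np.isnan(x).any():
        raise ValueError("filtered signal contains NaN")
    analytic = x if np.iscomplexobj(x) else sps.hilbert(x, axis=-1)
    phase = np.mod(np.angle(analytic), TWO_PI)
    # angles indistinguishable from 2*pi wrap to 0 (half-open convention)
    phase[phase > TWO_PI - 1e-9] = 0.0
    return PhaseSeries(phase=phase, amplitude=np.abs(analytic), band=band)


def extract_phase(lfp: np.ndarray, spec: FilterSpec) -> PhaseSeries:
    """Convenience: band-pass then take the instantaneous phase."""
    return instantaneous_phase(bandpass(lfp, spec), band=spec)


def intertrial_phase_coherence(phase: PhaseSeries | np.ndarray) -> np.ndarray:
    """Resultant length of the trial-averaged unit phasor, per sample.

    ``ITC(t) = |<exp(i*phi_trial(t))>_trials|`` in ``[0, 1]``; 1 means the
    phase is identical across trials, 0 a fully dispersed phase.
    """
    arr = phase.phase if isinstance(phase, PhaseSeries) else np.atleast_2d(np.asarray(phase))
    if arr.shape[0] < 2:
        raise ValueError("phase coherence requires at least 2 trials")
    return np.abs(np.exp(1j * arr).mean(axis=0))


def window_coherence(phase: PhaseSeries | np.ndarray, window_start: float, T: float) -> float:
    """Mean ITC over the window ``[window_start, window_start + T)`` in ms."""
    itc = intertrial_phase_coherence(phase)
    start = int(round(window_start))
    stop = int(round(window_start + T))
    if start < 0 or stop > itc.size or stop <= start:
        raise ValueError("coherence window out of range")
    return float(itc[start:stop].mean())
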