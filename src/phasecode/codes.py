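"""Construction of per-window response vectors for each candidate code.

Five codes are defined on the spikes inside a window ``[start, start + T)``:

``time``
    counts in N equally spaced, stimulus-locked time bins (half-open).
``phase``
    counts in N equally spaced bins of the instantaneous oscillation phase
    at the time of each spike (half-open; phase exactly 2*pi wraps to 0).
``count_shuffled``
    a random permutation of the time-partitioned bins; destroys temporal
    order while preserving the total count and the dimensionality.
``count_scalar``
    the total spike count as a length-1 vector.
``dual``
    the concatenation of the time- and phase-partitioned vectors.

The phase at a spike time is the phase at the nearest 1 ms sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_processing import FilterSpec, PhaseSeries, TWO_PI

__all__ = [
    "CodeSpec",
    "ResponseVector",
    "time_partitioned",
    "phase_partitioned",
    "spike_count_shuffled",
    "spike_count_scalar",
    "dual_code",
]

CODE_KINDS = ("time", "phase", "count_shuffled", "count_scalar", "dual")


@dataclass(frozen=True)
class CodeSpec:
    """Which code to build, with its window length T (ms) and bin count N."""

    kind: str = "time"
    N: int = 8
    T: float = 160.0
    band: FilterSpec | None = None
    shuffle_repeats: int = 20

    def __post_init__(self) -> None:
        if self.kind not in CODE_KINDS:
            raise ValueError(f"unknown code kind {self.kind!r}")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.shuffle_repeats < 1:
            raise ValueError("shuffle_repeats must be >= 1")
        if self.kind in ("phase", "dual") and self.band is None:
            object.__setattr__(self, "band", FilterSpec())

    @property
    def dimension(self) -> int:
        return {"count_scalar": 1, "dual": 2 * self.N}.get(self.kind, self.N)


@dataclass
class ResponseVector:
    """Counts-per-bin representation of one trial's response in one window."""

    counts: np.ndarray
    window_start: float
    code: CodeSpec | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _in_window(spike_times: np.ndarray, start: float, T: float) -> np.ndarray:
    times = np.asarray(spike_times, dtype=float)
    lo = np.searchsorted(times, start, side="left")
    hi = np.searchsorted(times, start + T, side="left")
    return times[lo:hi]


def _time_counts(spike_times: np.ndarray, start: float, N: int, T: float) -> np.ndarray:
    t = _in_window(spike_times, start, T)
    if t.size == 0:
        return np.zeros(N, dtype=int)
    bins = np.minimum(((t - start) * N / T).astype(int), N - 1)
    return np.bincount(bins, minlength=N)


def _phase_at(phase_row: np.ndarray, times: np.ndarray) -> np.ndarray:
    idx = np.clip(np.rint(times).astype(int), 0, phase_row.size - 1)
    return phase_row[idx]


def _phase_counts(
    spike_times: np.ndarray, phase_row: np.ndarray, start: float, N: int, T: float
) -> np.ndarray:
    t = _in_window(spike_times, start, T)
    if t.size == 0:
        return np.zeros(N, dtype=int)
    phi = _phase_at(phase_row, t)
    bins = np.minimum((phi * N / TWO_PI).astype(int), N - 1)  # 2*pi wraps to bin 0 upstream
    return np.bincount(bins, minlength=N)


def time_partitioned(
    spike_times: np.ndarray, window_start: float, N: int = 8, T: float = 160.0
) -> ResponseVector:
    """Counts in N stimulus-locked time bins; bin i covers
    ``[start + i*T/N, start + (i+1)*T/N)``."""
    counts = _time_counts(np.sort(np.asarray(spike_times, dtype=float)), window_start, N, T)
    return ResponseVector(counts, window_start, CodeSpec("time", N=N, T=T))


def phase_partitioned(
    spike_times: np.ndarray,
    phase: PhaseSeries | np.ndarray,
    window_start: float,
    N: int = 8,
    T: float = 160.0,
) -> ResponseVector:
    """Counts in N phase bins; each in-window spike is allocated to the bin
    of its instantaneous phase, bin i covering ``[i*2*pi/N, (i+1)*2*pi/N)``.

    ``phase`` is one trial's phase trace (a 1-D array or a single-trial
    :class:`PhaseSeries`), sampled at 1 ms and covering the window.
    """
    row = phase.phase[0] if isinstance(phase, PhaseSeries) else np.asarray(phase, dtype=float)
    if row.ndim != 1:
        raise ValueError("phase must be a single trial's 1-D phase trace")
    if row.size < window_start + T:
        raise ValueError("phase series shorter than the requested window")
    counts = _phase_counts(
        np.sort(np.asarray(spike_times, dtype=float)), row, window_start, N, T
    )
    return ResponseVector(counts, window_start, CodeSpec("phase", N=N, T=T))


def spike_count_shuffled(
    time_vector: ResponseVector, rng: np.random.Generator
) -> ResponseVector:
    """Permute the bins of a time-partitioned vector (without replacement).

    One shuffle realizes the spike-count code at the dimensionality of the
    partitioned codes; decoding results are averaged over
    ``shuffle_repeats`` independent shuffles downstream.
    """
    if time_vector.code is not None and time_vector.code.kind != "time":
        raise ValueError("spike_count_shuffled expects a time-partitioned vector")
    counts = rng.permutation(time_vector.counts)
    spec = time_vector.code
    code = CodeSpec("count_shuffled", N=counts.size, T=spec.T if spec else 160.0)
    return ResponseVector(counts, time_vector.window_start, code)


def spike_count_scalar(
    spike_times: np.ndarray, window_start: float, T: float = 160.0
) -> ResponseVector:
    """Total number of spikes in the window, as a length-1 vector."""
    t = _in_window(np.sort(np.asarray(spike_times, dtype=float)), window_start, T)
    return ResponseVector(np.array([t.size]), window_start, CodeSpec("count_scalar", N=1, T=T))


def dual_code(time_vector: ResponseVector, phase_vector: ResponseVector) -> ResponseVector:
    """Concatenate time- and phase-partitioned vectors from the same window."""
    if time_vector.window_start != phase_vector.window_start:
        raise ValueError("dual code requires vectors from the same window")
    if time_vector.counts.size != phase_vector.counts.size:
        raise ValueError("dual code requires the same N in both vectors")
    N = time_vector.counts.size
    T = time_vector.code.T if time_vector.code else 160.0
    counts = np.concatenate([time_vector.counts, phase_vector.counts])
    return ResponseVector(counts, time_vector.window_start, CodeSpec("dual", N=N, T=T))
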