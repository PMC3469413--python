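"""Epoch sampling and the decoding experiments built on top of it.

The continuous recording is treated as a stream from which K non-overlapping
epochs of length T are drawn at random; the epochs act as the "stimuli" of a
decoding problem and the stimulus repeats as the trials.  Every experiment
averages decoding performance over independently re-drawn epoch sets, and is
bit-reproducible from ``(recording config, seed)``.

Experiments provided:

* :func:`run_comparison` -- decode several codes on shared epoch sets,
  optionally with a temporally jittered codebook (uncertainty J).
* :func:`jitter_robustness` -- performance of each code as a function of J.
* :func:`frequency_sweep` -- chance-subtracted phase/count performance ratio
  as a function of the band used to derive the phase.
* :func:`parameter_sweep` -- performance along the T and N axes.
* :func:`noise_level_experiment` -- performance when a trial-unique
  background rate component is mixed in at relative dB levels.
* :func:`coherence_performance_correlation` -- correlation of per-epoch
  phase coherence with per-epoch decoding accuracy.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import codes as _codes
from .codes import CodeSpec
from .decoders import ClassifierSpec, DecodingResult, ResponseEnsemble, loo_decode
from .rng import stream
from .signal_processing import FilterSpec, PhaseSeries, extract_phase, window_coherence
from .synthetic import GeneratorConfig, Recording, generate_dataset

__all__ = [
    "EpochSet",
    "JitterSpec",
    "ComparisonResult",
    "sample_epochs",
    "build_response_arrays",
    "decode_code",
    "run_comparison",
    "jitter_robustness",
    "frequency_sweep",
    "parameter_sweep",
    "noise_level_experiment",
    "coherence_performance_correlation",
]


@dataclass(frozen=True)
class EpochSet:
    """K non-overlapping window starts (ms) of common length T."""

    starts: tuple[int, ...]
    T: float

    def __post_init__(self) -> None:
        s = np.sort(np.asarray(self.starts, dtype=float))
        if np.any(np.diff(s) < self.T):
            raise ValueError("epochs overlap")

    @property
    def K(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class JitterSpec:
    """Maximal temporal uncertainty J (ms); per-trial lags are uniform on
    [-J/2, +J/2]."""

    J: float = 0.0

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ValueError("J must be non-negative")


def sample_epochs(
    valid_range: tuple[float, float],
    K: int = 10,
    T: float = 160.0,
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """Draw K non-overlapping starts uniformly from ``valid_range``.

    Implemented by the order-statistics construction (sorted slack offsets
    plus stacked windows), which samples the uniform distribution over
    non-overlapping placements directly and still works when the windows
    tile the range exactly.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lo, hi = valid_range
    slack = (hi - lo) - K * T
    if slack < 0:
        raise ValueError(
            f"cannot place {K} non-overlapping windows of {T} ms in [{lo}, {hi})"
        )
    offsets = np.sort(rng.integers(0, int(slack) + 1, size=K))
    starts = (int(round(lo)) + offsets + np.arange(K) * int(round(T))).astype(int)
    return EpochSet(starts=tuple(int(s) for s in starts), T=T)


def _draw_lags(rng: np.random.Generator, shape: tuple[int, ...], J: float) -> np.ndarray:
    """i.i.d. uniform lags on [-J/2, +J/2]."""
    return (rng.random(shape) - 0.5) * J


def build_response_arrays(
    spikes: list[np.ndarray],
    code: CodeSpec,
    epoch_set: EpochSet,
    phase: PhaseSeries | None = None,
    lags: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Per-epoch ``(n_trials, dim)`` count arrays for one code.

    ``lags`` (shape ``(K, n_trials)``) shifts the extraction window of each
    trial of each epoch; used for codebook jitter.  ``count_shuffled`` is
    built as plain time vectors here and shuffled at decode time.
    """
    kind = code.kind
    if kind in ("phase", "dual") and phase is None:
        raise ValueError(f"code kind {kind!r} requires a PhaseSeries")
    n_trials = len(spikes)
    out = []
    for k, start in enumerate(epoch_set.starts):
        arr = np.zeros((n_trials, code.dimension), dtype=int)
        for j, times in enumerate(spikes):
            s = start + (lags[k, j] if lags is not None else 0.0)
            if kind in ("time", "count_shuffled"):
                arr[j] = _codes._time_counts(times, s, code.N, code.T)
            elif kind == "count_scalar":
                arr[j, 0] = _codes._in_window(times, s, code.T).size
            elif kind == "phase":
                arr[j] = _codes._phase_counts(times, phase.phase[j], s, code.N, code.T)
            else:  # dual
                arr[j, : code.N] = _codes._time_counts(times, s, code.N, code.T)
                arr[j, code.N :] = _codes._phase_counts(
                    times, phase.phase[j], s, code.N, code.T
                )
        out.append(arr)
    return out


def _shuffle_arrays(arrays: list[np.ndarray], rng: np.random.Generator) -> list[np.ndarray]:
    """Independently permute the bins of every trial vector."""
    out = []
    for a in arrays:
        idx = rng.random(a.shape).argsort(axis=1)
        out.append(np.take_along_axis(a, idx, axis=1))
    return out


def _mean_results(results: list[DecodingResult]) -> DecodingResult:
    return DecodingResult(
        percent_correct=float(np.mean([r.percent_correct for r in results])),
        confusion=np.mean([r.confusion for r in results], axis=0),
        per_stimulus_accuracy=np.mean([r.per_stimulus_accuracy for r in results], axis=0),
    )


def decode_code(
    train_arrays: list[np.ndarray],
    code: CodeSpec,
    classifier: ClassifierSpec,
    rng_shuffles: np.random.Generator,
    rng_classifier: np.random.Generator,
    test_arrays: list[np.ndarray] | None = None,
) -> DecodingResult:
    """Decode one code's arrays; ``count_shuffled`` averages over fresh
    shuffles (the same permutations applied to codebook and test sides)."""
    if code.kind != "count_shuffled":
        test = None if test_arrays is None else ResponseEnsemble(test_arrays)
        return loo_decode(
            ResponseEnsemble(train_arrays), classifier, rng_classifier, test_ensemble=test
        )
    results = []
    for _ in range(code.shuffle_repeats):
        shuffled = _shuffle_arrays(train_arrays, rng_shuffles)
        test = None
        if test_arrays is not None:
            test = ResponseEnsemble(_shuffle_arrays(test_arrays, rng_shuffles))
        results.append(
            loo_decode(ResponseEnsemble(shuffled), classifier, rng_classifier, test_ensemble=test)
        )
    return _mean_results(results)


@dataclass
class ComparisonResult:
    """Tidy per-set and per-epoch tables from one comparison run."""

    table: pd.DataFrame  # code, classifier, set, percent_correct
    epochs: pd.DataFrame  # code, set, epoch, start, accuracy, coherence

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(["code", "classifier"])["percent_correct"]
        out = g.agg(["mean", "sem", "count"]).reset_index()
        return out.rename(columns={"mean": "mean_pc", "sem": "sem_pc", "count": "n_sets"})

    def mean_pc(self, code: str) -> float:
        return float(self.table.loc[self.table["code"] == code, "percent_correct"].mean())


def _phase_for_bands(recording: Recording, bands: list[FilterSpec]) -> dict[tuple, PhaseSeries]:
    cache: dict[tuple, PhaseSeries] = {}
    for band in bands:
        key = tuple(sorted(band.to_json().items()))
        if key not in cache:
            cache[key] = extract_phase(recording.lfp, band)
    return cache


def _band_key(band: FilterSpec) -> tuple:
    return tuple(sorted(band.to_json().items()))


def run_comparison(
    recording: Recording,
    code_specs: list[CodeSpec],
    classifier: ClassifierSpec = ClassifierSpec(),
    n_epochs: int = 10,
    n_sets: int = 100,
    seed: int = 0,
    jitter: JitterSpec = JitterSpec(0.0),
    coherence_band: FilterSpec | None = None,
    phase_cache: dict[tuple, PhaseSeries] | None = None,
) -> ComparisonResult:
    """Decode every code on ``n_sets`` shared sets of ``n_epochs`` epochs.

    All codes in one call must share a window length T.  Epochs are drawn
    from the range left free by the widest filter edge margin plus J/2, so
    jittered windows never touch edge-contaminated samples.  Epoch sets are
    independent across repetitions; non-overlap is enforced within a set.
    """
    T_values = {c.T for c in code_specs}
    if len(T_values) > 1:
        raise ValueError("all codes in one comparison must share T")
    T = T_values.pop()

    bands = [c.band for c in code_specs if c.kind in ("phase", "dual")]
    if coherence_band is not None:
        bands.append(coherence_band)
    elif bands:
        coherence_band = bands[0]
    if phase_cache is None:
        phase_cache = _phase_for_bands(recording, bands)
    else:
        phase_cache.update(_phase_for_bands(recording, [
            b for b in bands if _band_key(b) not in phase_cache
        ]))

    margin = max([b.edge_margin_ms for b in bands], default=0.0) + jitter.J / 2.0
    lo = math.ceil(margin)
    hi = recording.duration_ms - math.ceil(margin)

    ep_rng = stream(seed, "epochs")
    jit_rng = stream(seed, "jitter")
    shuf_rng = stream(seed, "shuffles")
    clf_rng = stream(seed, "classifier")

    rows = []
    epoch_rows = []
    coh_phase = phase_cache[_band_key(coherence_band)] if coherence_band is not None else None
    for s in range(n_sets):
        epoch_set = sample_epochs((lo, hi), K=n_epochs, T=T, rng=ep_rng)
        lags = (
            _draw_lags(jit_rng, (n_epochs, recording.n_trials), jitter.J)
            if jitter.J > 0
            else None
        )
        coherences = (
            [window_coherence(coh_phase, st, T) for st in epoch_set.starts]
            if coh_phase is not None
            else [np.nan] * n_epochs
        )
        for code in code_specs:
            phase = (
                phase_cache[_band_key(code.band)] if code.kind in ("phase", "dual") else None
            )
            test_arrays = build_response_arrays(recording.spikes, code, epoch_set, phase)
            if lags is not None:
                train_arrays = build_response_arrays(
                    recording.spikes, code, epoch_set, phase, lags=lags
                )
            else:
                train_arrays = test_arrays
            result = decode_code(
                train_arrays,
                code,
                classifier,
                shuf_rng,
                clf_rng,
                test_arrays=test_arrays if lags is not None else None,
            )
            rows.append(
                {
                    "code": code.kind,
                    "classifier": classifier.name,
                    "set": s,
                    "percent_correct": result.percent_correct,
                }
            )
            for e, (st, coh) in enumerate(zip(epoch_set.starts, coherences)):
                epoch_rows.append(
                    {
                        "code": code.kind,
                        "set": s,
                        "epoch": e,
                        "start": st,
                        "accuracy": float(result.per_stimulus_accuracy[e]),
                        "coherence": coh,
                    }
                )
    return ComparisonResult(table=pd.DataFrame(rows), epochs=pd.DataFrame(epoch_rows))


def jitter_robustness(
    recording: Recording,
    code_specs: list[CodeSpec],
    J_values: tuple[float, ...] = (0.0, 40.0, 80.0, 160.0),
    classifier: ClassifierSpec = ClassifierSpec(),
    n_epochs: int = 10,
    n_sets: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean performance of each code at each temporal uncertainty J.

    The same seed is reused across J values, so epoch sets and the
    underlying uniform lag draws are shared (common random numbers) and the
    J-dependence is estimated on paired samples.
    """
    frames = []
    for J in J_values:
        res = run_comparison(
            recording,
            code_specs,
            classifier,
            n_epochs=n_epochs,
            n_sets=n_sets,
            seed=seed,
            jitter=JitterSpec(J),
        )
        t = res.table.copy()
        t["J"] = J
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def frequency_sweep(
    recording: Recording,
    centers_hz: tuple[float, ...] = (4, 8, 12, 16, 20, 24, 28, 32),
    width_hz: float = 4.0,
    N: int = 8,
    T: float = 160.0,
    classifier: ClassifierSpec = ClassifierSpec(),
    n_epochs: int = 10,
    n_sets: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Chance-subtracted phase/count performance ratio per frequency band.

    Each band is ``center +- width/2`` (3rd-order Butterworth).  The same
    seed (hence the same epoch sets) is shared across bands and with the
    spike-count reference, so the sweep varies only the phase source.
    """
    from .stats_report import chance_subtracted_ratio

    chance = 100.0 / n_epochs
    count_res = run_comparison(
        recording, [CodeSpec("count_scalar", T=T)], classifier,
        n_epochs=n_epochs, n_sets=n_sets, seed=seed,
    )
    count_pc = count_res.mean_pc("count_scalar")
    rows = []
    for c in centers_hz:
        band = FilterSpec("butterworth", low_hz=c - width_hz / 2, high_hz=c + width_hz / 2)
        res = run_comparison(
            recording, [CodeSpec("phase", N=N, T=T, band=band)], classifier,
            n_epochs=n_epochs, n_sets=n_sets, seed=seed,
        )
        phase_pc = res.mean_pc("phase")
        rows.append(
            {
                "center_hz": c,
                "phase_pc": phase_pc,
                "count_pc": count_pc,
                "ratio": chance_subtracted_ratio(phase_pc, count_pc, chance),
            }
        )
    return pd.DataFrame(rows)


def parameter_sweep(
    recording: Recording,
    T_values: tuple[float, ...] = (80, 160, 240, 320, 400, 480),
    N_values: tuple[int, ...] = (2, 4, 8, 12, 16),
    band: FilterSpec | None = None,
    classifier: ClassifierSpec = ClassifierSpec(),
    n_epochs: int = 10,
    n_sets: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Performance along the two standard slices of the (T, N) grid:
    varying T at N = 8 and varying N at T = 160 ms."""
    band = band or FilterSpec()
    rows = []
    for T in T_values:
        specs = [
            CodeSpec("time", N=8, T=T),
            CodeSpec("phase", N=8, T=T, band=band),
            CodeSpec("count_scalar", T=T),
        ]
        res = run_comparison(recording, specs, classifier, n_epochs=n_epochs,
                             n_sets=n_sets, seed=seed)
        for code in ("time", "phase", "count_scalar"):
            rows.append({"sweep": "T", "value": T, "code": code,
                         "mean_pc": res.mean_pc(code)})
    for N in N_values:
        specs = [
            CodeSpec("time", N=N, T=160.0),
            CodeSpec("phase", N=N, T=160.0, band=band),
            CodeSpec("count_scalar", T=160.0),
        ]
        res = run_comparison(recording, specs, classifier, n_epochs=n_epochs,
                             n_sets=n_sets, seed=seed)
        for code in ("time", "phase", "count_scalar"):
            rows.append({"sweep": "N", "value": N, "code": code,
                         "mean_pc": res.mean_pc(code)})
    return pd.DataFrame(rows)


def noise_level_experiment(
    base_config: GeneratorConfig,
    code_specs: list[CodeSpec],
    levels_db: tuple[float | None, ...] = (None, 6.0, 0.0, -6.0),
    classifier: ClassifierSpec = ClassifierSpec(),
    n_epochs: int = 10,
    n_sets: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Decode each code at each relative background-noise level.

    All levels share the same master seed, hence the identical target rate
    profile and oscillation; only the trial-unique background component
    changes, making the noise effect a paired comparison.
    """
    rows = []
    for level in levels_db:
        config = dataclasses.replace(base_config, noise_level_db=level)
        recording = generate_dataset(config)
        res = run_comparison(
            recording, code_specs, classifier,
            n_epochs=n_epochs, n_sets=n_sets, seed=seed,
        )
        for code in {c.kind for c in code_specs}:
            rows.append(
                {
                    "noise_level_db": np.nan if level is None else level,
                    "label": "none" if level is None else f"{level:+g} dB",
                    "code": code,
                    "mean_pc": res.mean_pc(code),
                }
            )
    return pd.DataFrame(rows)


def coherence_performance_correlation(result: ComparisonResult) -> pd.DataFrame:
    """Correlate per-epoch phase coherence with per-epoch decoding accuracy.

    The correlation is computed within each epoch set (across its epochs)
    and then averaged over sets; both Pearson and rank (Spearman)
    coefficients are reported.  Sets with zero coherence or accuracy
    variance are flagged as degenerate and excluded from the mean; if all
    sets are degenerate the coefficients are NaN.
    """
    rows = []
    for code, group in result.epochs.groupby("code"):
        pearsons, spearmans, degenerate = [], [], 0
        for _, g in group.groupby("set"):
            coh = g["coherence"].to_numpy()
            acc = g["accuracy"].to_numpy()
            if np.isnan(coh).any() or coh.std() == 0 or acc.std() == 0:
                degenerate += 1
                continue
            pearsons.append(sstats.pearsonr(coh, acc).statistic)
            spearmans.append(sstats.spearmanr(coh, acc).statistic)
        rows.append(
            {
                "code": code,
                "pearson": float(np.mean(pearsons)) if pearsons else np.nan,
                "spearman": float(np.mean(spearmans)) if spearmans else np.nan,
                "n_sets": len(pearsons),
                "n_degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
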