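"""Derived performance metrics and across-unit summary statistics.

All performance inputs are percent correct in [0, 100] (the one canonical
unit used throughout the package).  Undefined ratios (denominator at or
below chance) are flagged by returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "excess_performance",
    "relative_excess",
    "chance_subtracted_ratio",
    "dual_gain",
    "paired_t",
    "population_tests",
    "PopulationTests",
]


def excess_performance(code_pc: float, count_pc: float) -> float:
    """Percentage points of performance a partitioning code adds over the
    spike count (same unit, classifier, and epochs)."""
    return code_pc - count_pc


def relative_excess(phase_pc: float, time_pc: float, count_pc: float) -> float:
    """Excess of the phase code expressed relative to the time code's
    excess, in percent: ``100 * (phase - count) / (time - count)``.

    NaN when the time code has no excess.  Population summaries average
    this per-unit ratio across units (a ratio of population means is also
    easily derived from the same inputs but is not the default).
    """
    denom = time_pc - count_pc
    if denom <= 0:
        return float("nan")
    return 100.0 * (phase_pc - count_pc) / denom


def chance_subtracted_ratio(phase_pc: float, count_pc: float, chance_pc: float) -> float:
    """Gain factor of the phase code over the spike count after subtracting
    chance: ``(phase - chance) / (count - chance)``; NaN when the count code
    does not exceed chance."""
    denom = count_pc - chance_pc
    if denom <= 0:
        return float("nan")
    return (phase_pc - chance_pc) / denom


def dual_gain(dual_pc: float, best_individual_pc: float, chance_pc: float) -> float:
    """Percent gain of the dual code over the better individual code,
    relative to that code's above-chance performance:
    ``100 * (dual - best) / (best - chance)``.  Negative values (overfitting
    of the doubled dimensionality) are allowed; NaN when the best code does
    not exceed chance."""
    denom = best_individual_pc - chance_pc
    if denom <= 0:
        return float("nan")
    return 100.0 * (dual_pc - best_individual_pc) / denom


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Paired t-test returning ``(t, p)``, with the degenerate zero-variance
    difference handled explicitly: identical samples give (0, 1), a
    constant nonzero difference gives (+-inf, 0)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if d.size < 2:
        raise ValueError("paired test requires at least 2 pairs")
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = sstats.ttest_rel(x, y)
    return float(t), float(p)


@dataclass
class PopulationTests:
    """Across-unit summaries: pairwise code comparisons and the correlation
    of per-unit excess values between the two partitioning schemes."""

    means: dict[str, float]
    sems: dict[str, float]
    pairwise_t: pd.DataFrame  # code_a, code_b, t, p (uncorrected), p_bonferroni
    excess_spearman_r: float
    excess_spearman_p: float
    n_units: int


def population_tests(per_unit: pd.DataFrame) -> PopulationTests:
    """Summarise a per-unit performance table.

    ``per_unit`` has one row per unit and one column per code (percent
    correct); a ``count`` column (either ``count_scalar`` or ``count``) is
    required for the excess correlation when ``time`` and ``phase`` are both
    present.  Pairwise paired t-tests are reported uncorrected (they are
    few) with a Bonferroni column alongside.
    """
    if len(per_unit) < 3:
        raise ValueError("population tests require at least 3 units")
    code_cols = [c for c in per_unit.columns if per_unit[c].dtype.kind in "fi"]
    means = {c: float(per_unit[c].mean()) for c in code_cols}
    sems = {c: float(per_unit[c].sem()) for c in code_cols}

    rows = []
    pairs = [(a, b) for i, a in enumerate(code_cols) for b in code_cols[i + 1 :]]
    for a, b in pairs:
        t, p = paired_t(per_unit[a].to_numpy(), per_unit[b].to_numpy())
        rows.append({"code_a": a, "code_b": b, "t": t, "p": p,
                     "p_bonferroni": min(p * len(pairs), 1.0)})
    pairwise = pd.DataFrame(rows)

    r = p_r = float("nan")
    count_col = next((c for c in ("count_scalar", "count") if c in per_unit), None)
    if count_col and "time" in per_unit and "phase" in per_unit:
        ex_time = per_unit["time"] - per_unit[count_col]
        ex_phase = per_unit["phase"] - per_unit[count_col]
        if ex_time.nunique() > 1 and ex_phase.nunique() > 1:
            res = sstats.spearmanr(ex_time, ex_phase)
            r, p_r = float(res.statistic), float(res.pvalue)

    return PopulationTests(
        means=means,
        sems=sems,
        pairwise_t=pairwise,
        excess_spearman_r=r,
        excess_spearman_p=p_r,
        n_units=len(per_unit),
    )
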