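"""Derived quantities and statistical comparisons.

Penetration efficiency of an imported oligonucleotide, absolute
concentration estimation from calibration spike-ins, replicate aggregation
(mean +/- SEM), two-group t-tests with Bonferroni correction, and
growth-curve AUC comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GrowthCurve",
    "SpikeInModel",
    "penetration_efficiency",
    "estimate_concentration",
    "aggregate_percentages",
    "compare_groups",
    "growth_auc",
]


@dataclass
class GrowthCurve:
    """Optical-density time course (OD at 650 nm versus hours)."""

    times: np.ndarray
    od: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise ValueError("times and od must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od must be nonnegative")


@dataclass
class SpikeInModel:
    """Spike-in counts from one secretome dataset.

    spike_total_conc is the combined molar concentration of all spike
    oligos (e.g. four oligos at 1 uM each = 4 uM total).
    """

    spike_total_conc: float
    n_spike_reads: int
    n_total_reads: int

    def __post_init__(self) -> None:
        if not (0 < self.n_spike_reads <= self.n_total_reads):
            raise ValueError("need 0 < n_spike_reads <= n_total_reads")
        if self.spike_total_conc <= 0:
            raise ValueError("spike_total_conc must be positive")


def penetration_efficiency(n_inside: int, n_outside: int) -> float:
    """Percentage of a tRF's reads found inside cells, out of inside+outside.

    Undefined (NaN) when both counts are zero.
    """
    total = n_inside + n_outside
    if total == 0:
        return math.nan
    return 100.0 * n_inside / total


def estimate_concentration(m: SpikeInModel) -> float:
    """Molar concentration of non-spike RNA from spike-in read counts.

    Assumes read counts are proportional to molar abundance, so
    conc = spike_total_conc * (n_total - n_spike) / n_spike.
    """
    return m.spike_total_conc * (m.n_total_reads - m.n_spike_reads) / m.n_spike_reads


def aggregate_percentages(values: list[float]) -> tuple[float, float | None]:
    """Mean and SEM (= sd/sqrt(n), sample sd) across replicates.

    With a single replicate the mean is returned and SEM is None.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, sem


def compare_groups(
    a: list[float],
    b: list[float],
    n_comparisons: int = 1,
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test with Bonferroni correction.

    Welch's test by default (small replicate counts, unknown variances);
    ``equal_var=True`` restores the pooled test. p_adjusted =
    min(1, p * n_comparisons). Degenerate inputs (both groups constant)
    give p = 1 when the means agree and p = 0 otherwise, by convention.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs at least 2 values")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        if xa.mean() == xb.mean():
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, xa.mean() - xb.mean()), 0.0
    else:
        t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
        t, p = float(t), float(p)
    return t, p, min(1.0, p * n_comparisons)


def growth_auc(curve: GrowthCurve, interval: tuple[float, float]) -> float:
    """Trapezoidal area under the OD curve over [t0, t1] (OD x hours).

    Endpoints falling between samples are linearly interpolated; an empty
    interval (t0 == t1) gives 0.
    """
    t0, t1 = interval
    if t0 > t1:
        raise ValueError("interval must have t0 <= t1")
    if t0 < curve.times[0] or t1 > curve.times[-1]:
        raise ValueError("interval outside the measured time range")
    if t0 == t1:
        return 0.0
    inner = curve.times[(curve.times > t0) & (curve.times < t1)]
    grid = np.concatenate(([t0], inner, [t1]))
    vals = np.interp(grid, curve.times, curve.od)
    return float(np.trapezoid(vals, grid))
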